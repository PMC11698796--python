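"""Alignment strength S_align across self-propulsion speeds.

S_align averages the normalised post-interaction angle over a grid of
initial conditions: 1 means every tested pair ends perfectly aligned.
Some propulsion is necessary (nu = 0 stops interactions too early), but
too much lets cells push past each other.  A small grid is used here so
the sweep runs in about a minute; the analysis tools default to 20 x 20.
"""

from cellalign import ModelParams, alignment_map

print("nu     S_align   coverage   (r = 2, 10 x 10 grid)")
for nu in (0.0, 1.0, 2.0, 4.0, 8.0):
    amap = alignment_map(ModelParams(nu=nu, gamma=0.0, r_bar=2.0), grid_n=10)
    print(f"{nu:<5g}  {amap.S_align:.4f}    {amap.coverage:.3f}")

print(
    "\nS_align peaks at moderate speed: the non-monotone dependence on nu "
    "is the signature of the competition between interaction persistence "
    "and escape."
)
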