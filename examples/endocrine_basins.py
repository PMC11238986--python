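"""Map the three attractors of the mutually inhibitory HPG-HPA loop.

Each endocrine axis inhibits the other (significant at high hormone levels)
and limits itself.  The loop is tristable: a symmetric low-low state
(normal circadian operation) and an asymmetric pair where one axis
dominates.  The high-HPA/low-HPG member is the putative pathogenic state.
"""

from fmloop import basin_map, find_equilibria_endocrine

for eq in find_equilibria_endocrine():
    hpa, hpg = eq.state
    print(f"{eq.stability:>7} equilibrium at HPA={hpa:6.2f}, HPG={hpg:6.2f}"
          f"  (residual {eq.residual:.1e})")

bm = basin_map(resolution=21, horizon=8000.0)
print("\nbasin areas (fraction of the 21x21 grid over [0,100]^2):")
for idx, frac in bm.fractions.items():
    hpa, hpg = bm.stable_equilibria[idx].state
    print(f"  attractor (HPA={hpa:5.1f}, HPG={hpg:5.1f}): {frac:.2f}")
print("\nReading: the symmetric low-low basin is the widest — most endocrine")
print("histories relax to normal operation; only strongly asymmetric states")
print("(stress + neurosteroid withdrawal) reach the high-HPA/low-HPG corner.")
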