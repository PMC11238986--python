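"""Locate the monostable/bistable fold of the thalamocortical pain loop.

The loop couples the ventroposterolateral thalamic nucleus (VPL), primary
somatosensory cortex (SSC) and thalamic reticular nucleus (TRN).  Below a
critical GABAergic strength a_hat the loop acquires a second, high-firing
attractor — the putative chronic-pain state.  This script enumerates the
equilibria on both sides of the fold and sweeps a_hat across glutamatergic
strengths b.
"""

from fmloop import ThalamoParams, bifurcation_curve, bifurcation_point, find_equilibria

for a in (0.3, 0.2):
    eqs = find_equilibria(ThalamoParams(a=a, b=1.0))
    print(f"a={a}, b=1: "
          + "; ".join(f"{e.stability} at V={e.state[2]:.1f} Hz" for e in eqs))

res = bifurcation_point(b=1.0, theta=1.0)
print(f"\nfold at b=1: a_hat = {res.a_hat:.4f} (bracket width {res.tol})")

curve = bifurcation_curve([0.5, 0.6, 0.8, 1.0], theta=1.0)
print("\nfold location vs glutamatergic strength (nondecreasing):")
print(curve.to_string(index=False))
print("\nReading: stronger glutamatergic drive (larger b) moves the fold up,")
print("so less GABAergic weakening suffices to make the loop bistable.")
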