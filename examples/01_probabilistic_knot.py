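"""Probabilistic knot type of an open chain by stochastic closure.

A deeply knotted open curve (a cut trefoil with its ends pulled to the
hull) is closed through 100 points on a far sphere; the spectrum lists
the fraction of closure points yielding each knot type.
"""

from protknot import dominant_type, knot_spectrum
from protknot.fixtures import open_trefoil_curve, straight_curve

chain = open_trefoil_curve(n=60)
spectrum = knot_spectrum(chain, n=100)
print("open trefoil spectrum:")
for ktype, p in sorted(spectrum.probabilities.items(), key=lambda kv: -kv[1]):
    print(f"  {ktype.name:10s} {p:.2f}")
t, p = dominant_type(spectrum)
print(f"dominant: {t.name} at probability {p:.2f} -> the chain is knotted")

trivial = knot_spectrum(straight_curve(n=10), n=100)
print(f"\nstraight chain: {{'0_1': {trivial.probabilities[dominant_type(trivial)[0]]:.2f}}}"
      " -> every closure of an unentangled chain is the unknot")
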