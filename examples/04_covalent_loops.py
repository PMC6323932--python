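"""Deterministic knots in covalent loops.

Disulfide bridges close genuine loops through the backbone; such loops
have a unique knot type — no stochastic closure needed. This fixture is
a chain that is UNKNOTTED as a backbone yet carries a trefoil covalent
loop (the knotted stretch is bridged by a disulfide while the tail
retraces back out of the knot).
"""

from protknot import (
    dominant_type,
    enumerate_covalent_loops,
    extract_backbone,
    knot_spectrum,
    loop_knot_type,
    parse_loop_notation,
)
from protknot.fixtures import bridged_loop_chain

chain = bridged_loop_chain()
print(f"chain {chain.source_id}: {len(chain.residues)} residues, "
      f"bridges: {[(b.kind, b.res_a, b.res_b) for b in chain.bridges]}")

backbone, _ = extract_backbone(chain)
t, p = dominant_type(knot_spectrum(backbone, n=100))
print(f"backbone (probabilistic): {t.name} at p={p:.2f} -> not knotted as an open chain")

for loop in enumerate_covalent_loops(chain):
    result = loop_knot_type(loop)
    print(f"covalent loop {loop.notation}: {result.knot_type.name} "
          f"({loop.length_residues} residues) -> a deterministic trefoil")

bridge = parse_loop_notation("17-b-29")
print(f"\nnotation round trip: '17-b-29' -> disulfide bridge "
      f"Cys{bridge.res_a}-Cys{bridge.res_b}")
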