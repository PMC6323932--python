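"""Knotoid classification of an open chain over projection directions.

Knotoids classify open curves without closing them, but the type depends
on the projection direction, so the chain is characterized by the
distribution of knotoid types over 100 quasi-uniform directions and by
the projection globe (direction -> type map).
"""

from protknot import dominant_type, knotoid_distribution, projection_globe
from protknot.fixtures import open_trefoil_curve

chain = open_trefoil_curve(n=60)
dist = knotoid_distribution(chain, n_directions=100)
print("knotoid distribution (100 directions):")
for ktype, p in sorted(dist.probabilities.items(), key=lambda kv: -kv[1]):
    print(f"  {ktype.name:10s} {p:.2f}")
t, p = dominant_type(dist)
print(f"dominant: {t.name} at {p:.2f} -> the trefoil-type knotoid represents the chain")

globe = projection_globe(chain, resolution=100)
regions = {}
for _, _, name in globe.to_rows():
    regions[name] = regions.get(name, 0) + 1
print("\nprojection globe regions (directions per type):", regions)
print("each point of the globe is one viewing direction; the dominant type "
      "occupies the largest area")
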