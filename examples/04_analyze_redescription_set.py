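"""Post-hoc analysis of a mined set: label homogeneity and attribute pairs.

Mines a dataset with two differently-labelled plants, then reports the
support-set entropy of each redescription (0 bits = a diagnosis-homogeneous
group) and the attribute pairs that co-occur across redescription queries,
with their raw-data correlation.
"""

from redescribe import EngineConfig, QualityConstraints, mine
from redescribe.analysis import cooccurrence, pair_correlation, support_entropy
from redescribe.synthetic import Plant, PlantSpec, generate

data, truths = generate(PlantSpec(
    n_instances=500, n_attrs1=10, n_attrs2=10,
    plants=(Plant(size=90, k1=1, k2=1, label="AD"),
            Plant(size=90, k1=1, k2=1, label="CN")),
    seed=3))

config = EngineConfig(
    max_iter=10,
    quality=QualityConstraints(min_jaccard=0.5, max_pvalue=0.01,
                               support_interval=(40, 200)),
    seed=1, set_capacity=50)
rset = mine(data, config)
print(f"mined {len(rset)} redescriptions\n")

print("support-set entropy (bits) of the five largest supports:")
for r in sorted(rset, key=lambda r: -r.support_size)[:5]:
    h = support_entropy(r, data.labels)
    print(f"  |E11| = {r.support_size:3d}  H = {h:.3f}")

view_map = {a.name: ("clin" if a.view == 1 else "bio")
            for a in data.attributes()}
tables = cooccurrence(rset, view_map)
print("\ntop co-occurring attribute pairs (bio-clin):")
for a, b, count in tables.get("bio-clin").rows[:5]:
    method, coef, p = pair_correlation(
        data.view1[a] if a.startswith("clin") else data.view2[a],
        data.view1[b] if b.startswith("clin") else data.view2[b])
    print(f"  {a}, {b}: {count} co-occurrences; "
          f"{method} correlation {coef:+.2f} (p = {p:.2g})")

print()
print("Low entropy marks label-homogeneous subgroups; recurring attribute")
print("pairs across many redescriptions point at robust cross-view links.")
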