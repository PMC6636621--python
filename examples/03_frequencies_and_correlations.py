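"""Distribution classes and index correlation structure.

Shows (a) the relative-frequency classes of stressed yield with the
genotypes in each class, and (b) which indices correlate with yield in
each environment — indices correlated with both Yp and Ys (typically STI,
MP, GMP, HM) are the ones able to find genotypes that perform everywhere.
"""

import stressidx as sx

trial = sx.generate_trial(n=40, seed=3)
table = sx.compute_indices(trial)

fd = sx.frequency_distribution(trial.ys, trial.genotypes, variable="Ys")
print(f"Stressed yield ({trial.units}) in {fd.n_bins} classes:")
for label, count, rel, members in zip(fd.intervals(), fd.counts, fd.relative, fd.members):
    shown = ", ".join(members[:5]) + (", ..." if len(members) > 5 else "")
    print(f"  {label:>16}: {count:2d} genotypes ({100 * rel:4.1f}%)  {shown}")

pearson = sx.pearson_matrix(table, trial)
print("\nPearson correlation of each index with yield (values, * p<0.05, ** p<0.01):")
spec = sx.heatmap_data(pearson)
for idx in ("TOL", "MP", "GMP", "HM", "SSI", "STI", "YI", "YSI", "RSI"):
    row = []
    for env in ("Yp", "Ys"):
        row.append(f"{env}: {pearson.r.loc[idx, env]:+.2f}{spec.stars.loc[idx, env]}")
    print(f"  {idx:<4} {row[0]:<12} {row[1]}")
print("\nIndices significant against BOTH columns can separate group-A genotypes.")
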