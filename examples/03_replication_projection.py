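"""Replicate a discovery linkage on an independent cohort by projection.

Fits the fusion on a discovery cohort (n = 400), then generates an
independent 166-subject cohort sharing the same spatial/genetic sources,
projects it onto the discovery sources with the Moore-Penrose pseudoinverse,
and re-tests the pairwise linkage on the projected loadings.
"""

import warnings
from dataclasses import replace

from parafuse import (
    CohortConfig,
    FusionConfig,
    MODALITIES,
    fit_parafusion,
    generate_linked_cohort,
    prepare_features,
    project_loadings,
    replicate_linkage,
)

warnings.simplefilter("ignore")

config = CohortConfig(n_subjects=400, n_sites=2)
features, phenotypes, truth = generate_linked_cohort(config, seed=5)
prepared = {m: prepare_features(features[m], phenotypes) for m in MODALITIES}
result = fit_parafusion(
    prepared["fALFF"], prepared["GM"], prepared["SNP"],
    orders=config.n_components, config=FusionConfig(seed=11),
)

cfg2 = replace(config, n_subjects=166, n_sites=1, n_hc=87)
features2, phenotypes2, _ = generate_linked_cohort(cfg2, seed=7, sources=truth.sources)
projected = {
    m: project_loadings(prepare_features(features2[m], phenotypes2), result.sources(m))
    for m in MODALITIES
}
report = replicate_linkage(projected, phenotypes2, triplet=result.triplet)

print(f"replication cohort n = {report.extras['n']}")
i, j, k = result.triplet
triplet_rows = report.pairs.set_index(
    ["modality_a", "modality_b", "comp_a", "comp_b"]
)
print("projected triplet correlations (Bonferroni over the 3 replication tests):")
for (a, b), (ca, cb) in zip(
    [("fALFF", "GM"), ("fALFF", "SNP"), ("GM", "SNP")], [(i, j), (i, k), (j, k)]
):
    row = triplet_rows.loc[(a, b, ca, cb)]
    mark = "*" if row["p"] < 0.05 / 3 else " "
    print(f"  {a:>6s}-{b:<5s} r = {row['r']:+.3f}  p = {row['p']:.2e} {mark}")
for pair, (r, p) in report.extras["partial_given_diagnosis"].items():
    print(f"  {pair[0]:>6s}-{pair[1]:<5s} partial r given diagnosis = {r:+.3f} (p = {p:.2e})")
# replicated correlations mean the linked pattern generalizes to subjects the
# fusion never saw
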