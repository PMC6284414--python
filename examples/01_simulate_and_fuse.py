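"""Generate a linked tri-modal cohort and recover its triplet by fusion.

Builds a 400-subject synthetic cohort with one planted fALFF-GM-SNP linked
component (loading correlations 0.75 / 0.17 / 0.17), prepares the three
feature matrices (site normalization + covariate regression), fits the
three-way parallel ICA, and prints the recovered triplet correlations next to
the generating targets plus how well each planted source was recovered.
"""

import warnings

import numpy as np

from parafuse import (
    CohortConfig,
    FusionConfig,
    MODALITIES,
    fit_parafusion,
    generate_linked_cohort,
    match_sources,
    prepare_features,
)

warnings.simplefilter("ignore")

config = CohortConfig(n_subjects=400, n_sites=2)
features, phenotypes, truth = generate_linked_cohort(config, seed=5)
prepared = {m: prepare_features(features[m], phenotypes) for m in MODALITIES}

result = fit_parafusion(
    prepared["fALFF"], prepared["GM"], prepared["SNP"],
    orders=config.n_components, config=FusionConfig(seed=11),
)

print("linked triplet (component indices):", result.triplet)
targets = dict(zip([("fALFF", "GM"), ("fALFF", "SNP"), ("GM", "SNP")],
                   config.target_corrs))
for pair, r in result.triplet_corrs.items():
    print(f"  {pair[0]:>6s}-{pair[1]:<5s} r = {r:+.3f}   (target {targets[pair]:+.2f})")
for m in MODALITIES:
    _, corrs = match_sources(result.sources(m), truth.sources[m])
    print(f"{m:>6s}: mean |r| between estimated and planted sources = {corrs.mean():.3f}")
# correlations near their targets and source recovery near 1 mean the fusion
# found the planted cross-modality pattern, not an artifact of the coupling
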