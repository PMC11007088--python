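import numpy as np
import pandas as pd
import pytest

from cvdstrat.io import GenotypeMatrix, WeightPanel
from cvdstrat.simulate import generate_study


def make_geno(dosages, effect_alleles=None, other_alleles=None, maf=None,
              call_rate=None, hwe_p=None, info=None) -> GenotypeMatrix:
    """Hand-build a GenotypeMatrix with explicit metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(m)],
        "chrom": ["1"] * m,
        "pos": np.arange(1, m + 1),
        "effect_allele": effect_alleles or ["A"] * m,
        "other_allele": other_alleles or ["G"] * m,
        "maf": maf if maf is not None else np.full(m, 0.3),
        "call_rate": call_rate if call_rate is not None else np.ones(m),
        "hwe_p": hwe_p if hwe_p is not None else np.ones(m),
        "info_quality": info if info is not None else np.ones(m),
    })
    return GenotypeMatrix(dosages, [f"s{i}" for i in range(n)], variants)


def make_panel(trait, variant_ids, weights, effect_alleles=None) -> WeightPanel:
    return WeightPanel(trait, pd.DataFrame({
        "variant_id": variant_ids,
        "effect_allele": effect_alleles or ["A"] * len(variant_ids),
        "weight": weights,
    }))


@pytest.fixture(scope="session")
def small_study():
    """A scaled-down cohort with the default (additive-signal) preset."""
    return generate_study("table1", seed=11, n_samples=2500, n_variants=80,
                          n_causal_per_trait=15)


@pytest.fixture(scope="session")
def small_analysis(small_study):
    """Analysis frame for the small study: scores, groups, exclusions applied."""
    from tests.helpers import build_analysis_frame

    return build_analysis_frame(small_study)
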