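import math

import numpy as np
import pytest

import gmdrprs as g


@pytest.fixture(scope="session")
def planted_pair_cohort():
    """Balanced case-control cohort with one strongly penetrant planted
    two-SNP interaction among otherwise-null SNPs (10 SNPs, MAF 0.3)."""
    specs = [g.SNPSpec(id=f"s{i}", maf=0.3) for i in range(10)]
    model = g.EffectModel(
        intercept=math.log(0.05 / 0.95),
        epistasis_cells={("s0", "s1"): g.checkerboard_epistasis(math.log(3.5))},
    )
    return g.simulate_case_control(2000, 2000, specs, model, seed=20240927)


@pytest.fixture(scope="session")
def null_cohort():
    """Moderate cohort with no genetic effects (for calibration checks)."""
    specs = [g.SNPSpec(id=f"n{i}", maf=0.25) for i in range(20)]
    model = g.EffectModel(intercept=math.log(0.1 / 0.9))
    return g.simulate_cohort(specs, 4000, model, seed=7)


def hwe_enumeration_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Independent brute-force HWE exact p: direct multinomial enumeration
    of every heterozygote count compatible with the allele-count margins."""
    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    if min(nA, na) == 0:
        return 1.0

    def logprob(h):
        r = (min(nA, na) - h) // 2        # rare homozygotes
        c = n - h - r                     # common homozygotes
        return (math.lgamma(n + 1) - math.lgamma(r + 1) - math.lgamma(h + 1)
                - math.lgamma(c + 1) + h * math.log(2)
                + math.lgamma(nA + 1) + math.lgamma(na + 1)
                - math.lgamma(2 * n + 1))

    hets = range(min(nA, na) % 2, min(nA, na) + 1, 2)
    probs = {h: math.exp(logprob(h)) for h in hets}
    total = sum(probs.values())
    p_obs = probs[n_Aa] / total
    return min(1.0, sum(p for p in probs.values() if p / total <= p_obs * (1 + 1e-12)))


@pytest.fixture(scope="session")
def hwe_oracle():
    return hwe_enumeration_oracle
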