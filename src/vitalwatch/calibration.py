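"""Monte-Carlo calibration of the group-comparison tests.

Runs the full generate -> preprocess -> detect -> normalize -> test
pipeline on repeated synthetic cohorts and records how often each test
rejects at a given significance level.  Under the ``null`` scenario —
group labels are a pure random labelling of identically distributed
exposures — the rejection rate estimates the tests' actual size; under an
effect scenario it estimates power.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pipeline import analyze_cohort
from .simulate import CohortSimParams, generate_cohort
from .stats import chi_square_test, kruskal_wallis_test


@dataclass
class RejectionRates:
    n_replicates: int
    alpha: float
    chi2_rejections: int
    kw_rejections: int
    n_degenerate: int  # replicates whose contingency table was degenerate

    @property
    def chi2_rate(self) -> float:
        return self.chi2_rejections / self.n_replicates

    @property
    def kw_rate(self) -> float:
        return self.kw_rejections / self.n_replicates


def replicate_pvalues(params: CohortSimParams, tier_label: str):
    """One replicate: (chi-square p for the tier, KW p for total duration).

    A degenerate contingency table (an all-zero row makes the chi-square
    statistic undefined) yields ``None`` for the chi-square p-value.
    """
    records = generate_cohort(params)
    result = analyze_cohort(records)
    try:
        table, _ = result.tier_contingency(tier_label)
        chi_p = chi_square_test(table.to_array()).p_value
    except ValueError:
        chi_p = None
    vals = result.duration_values(None)
    groups = [v for v in vals.values() if len(v)]
    kw_p = kruskal_wallis_test(groups).p_value if len(groups) >= 2 else None
    return chi_p, kw_p


def rejection_rates(
    base_params: CohortSimParams,
    tier_label: str,
    n_replicates: int,
    base_seed: int = 0,
    alpha: float = 0.05,
) -> RejectionRates:
    """Rejection rates of the chi-square (given tier) and Kruskal-Wallis
    (total abnormal duration) comparisons over repeated cohorts.

    Replicate ``i`` reruns the scenario with seed ``base_seed + i``; a
    degenerate replicate counts as a non-rejection for the chi-square test.
    """
    chi_rej = kw_rej = degen = 0
    for i in range(n_replicates):
        params = base_params.model_copy(update={"seed": base_seed + i})
        chi_p, kw_p = replicate_pvalues(params, tier_label)
        if chi_p is None:
            degen += 1
        elif chi_p < alpha:
            chi_rej += 1
        if kw_p is not None and kw_p < alpha:
            kw_rej += 1
    return RejectionRates(
        n_replicates=n_replicates, alpha=alpha,
        chi2_rejections=chi_rej, kw_rejections=kw_rej, n_degenerate=degen,
    )
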