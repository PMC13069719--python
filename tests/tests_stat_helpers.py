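"""Small statistical helpers shared by tests and the acceptance suite."""

from statsmodels.stats.proportion import proportion_confint


def binom_ci(successes: int, n: int, alpha: float = 0.05):
    """Exact (Clopper-Pearson) binomial confidence interval."""
    return proportion_confint(successes, n, alpha=alpha, method="beta")
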