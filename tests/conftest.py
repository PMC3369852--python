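import pytest

from indelassoc import studydata


@pytest.fixture(scope="session")
def table3_calls():
    return studydata.table3_calls()


@pytest.fixture(scope="session")
def study_cohort():
    """Synthetic per-patient reconstruction of the published study tables."""
    return studydata.study_fixture_cohort(seed=0)


def fisher_oracle(a, b, c, d):
    """Exhaustive fixed-margin two-sided Fisher p with exact rational
    arithmetic: sum of hypergeometric point probabilities no larger than
    the observed one."""
    from fractions import Fraction
    from math import comb

    r1, r2, k = a + b, c + d, a + c
    denom = comb(r1 + r2, k)
    support = range(max(0, k - r2), min(k, r1) + 1)
    pmf = {x: Fraction(comb(r1, x) * comb(r2, k - x), denom) for x in support}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs))
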