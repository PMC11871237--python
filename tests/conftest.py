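import numpy as np
import pytest

from lrscape.lrpairs import SurvivalTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


def random_survival(rng, n, censor_frac=0.3, endpoint="OS"):
    """Small random right-censored survival table for oracle tests."""
    time = rng.exponential(100.0, size=n) + 0.5
    event = (rng.random(n) > censor_frac).astype(int)
    samples = np.array([f"S{i}" for i in range(n)])
    return SurvivalTable(samples, time, event, endpoint)


def naive_maxstat(scores, surv, minprop=0.3, maxprop=0.7):
    """Independent brute-force maximally selected log-rank statistic.

    Nelson-Aalen cumulative hazard from lifelines, log-rank scores
    a_i = event_i - H(t_i), then a per-split python loop over every distinct
    score value, standardizing the low-group score sum with permutation
    moments. Returns (cutoff, max |Z|).
    """
    from lifelines import NelsonAalenFitter

    scores = np.asarray(scores, float)
    n = len(scores)
    naf = NelsonAalenFitter(nelson_aalen_smoothing=False).fit(surv.time, surv.event)
    cumhaz = naf.cumulative_hazard_at_times(surv.time).to_numpy()
    a = surv.event - cumhaz
    sigma2 = np.sum((a - a.mean()) ** 2) / n
    best = (None, -1.0)
    for cut in sorted(set(scores.tolist()))[:-1]:
        low = scores <= cut
        m = int(low.sum())
        if not (minprop <= m / n <= maxprop):
            continue
        s = a[low].sum() - m * a.mean()
        z = abs(s) / np.sqrt(m * (n - m) / (n - 1) * sigma2)
        if z > best[1] + 1e-12:
            best = (cut, z)
    return best
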