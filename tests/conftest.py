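import numpy as np
import pytest

from transddi import GroundTruth, defaults


@pytest.fixture(scope="session")
def perpetrators():
    return defaults.load_perpetrators()


@pytest.fixture(scope="session")
def ki_summaries():
    return defaults.load_ki_summaries()


@pytest.fixture(scope="session")
def victim():
    return defaults.load_victim_model()


@pytest.fixture(scope="session")
def predictions():
    return defaults.predict_all()


@pytest.fixture
def clean_truth():
    """Noise-free ground truth for exact round-trip checks."""
    return GroundTruth(ic50=10.0, hill=1.0, noise_cv=0.0, occasion_cv=0.0)


@pytest.fixture
def conc_series():
    """Seven-point log series bracketing an IC50 of 10 μM."""
    return [0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0]


def grid_search_4pl(conc, y, ic50_lo, ic50_hi, n_ic50=400, n_hill=50,
                    hill_lo=0.2, hill_hi=5.0):
    """Independent brute-force 4PL oracle.

    Exhaustive search over a log grid of (IC50, Hill); at each grid point
    the plateaus (top, bottom) are the exact linear least-squares solution,
    since the model is linear in them once the logistic fraction is fixed.
    Returns (ic50, hill, top, bottom, rss) at the grid minimum plus the
    log10 grid spacing of the IC50 axis.
    """
    conc = np.asarray(conc, float)
    y = np.asarray(y, float)
    ic50s = np.logspace(np.log10(ic50_lo), np.log10(ic50_hi), n_ic50)
    hills = np.logspace(np.log10(hill_lo), np.log10(hill_hi), n_hill)
    best = None
    for h in hills:
        with np.errstate(divide="ignore"):
            frac = 1.0 / (1.0 + np.where(conc > 0, conc[None, :] / ic50s[:, None], 0.0) ** h)
        # linear LSQ in (top, bottom): y ~ top*f + bottom*(1-f)
        g = 1.0 - frac
        a = (frac * frac).sum(axis=1)
        b = (frac * g).sum(axis=1)
        d = (g * g).sum(axis=1)
        r1 = (frac * y).sum(axis=1)
        r2 = (g * y).sum(axis=1)
        det = a * d - b * b
        det = np.where(np.abs(det) < 1e-30, np.nan, det)
        top = (d * r1 - b * r2) / det
        bottom = (a * r2 - b * r1) / det
        pred = top[:, None] * frac + bottom[:, None] * g
        rss = ((pred - y[None, :]) ** 2).sum(axis=1)
        i = np.nanargmin(rss)
        if best is None or rss[i] < best[4]:
            best = (ic50s[i], h, top[i], bottom[i], rss[i])
    step = (np.log10(ic50_hi) - np.log10(ic50_lo)) / (n_ic50 - 1)
    return best + (step,)
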