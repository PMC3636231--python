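import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


def entries_frame(days, weights, member_id="M1", start_id=1):
    """Build a weight-entry frame for one member."""
    return pd.DataFrame({
        "entry_id": [f"{member_id}-E{start_id + i}" for i in range(len(days))],
        "member_id": member_id,
        "day": list(days),
        "weight_lb": list(weights),
    })


def members_frame(member_ids, **overrides):
    n = len(member_ids)
    base = {
        "member_id": list(member_ids),
        "age": [35.0] * n,
        "sex": ["female"] * n,
        "height_in": [65.0] * n,
        "weight_lb": [180.0] * n,
        "reg_date": [0] * n,
        "reg_source": ["other"] * n,
        "region": ["US-South"] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


@pytest.fixture
def one_member():
    return members_frame(["M1"])


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept free of the package's filter code)

def oracle_quadratic_flags(days, weights, sd_mult=3.0, abs_lb=10.0):
    """Quadratic OLS via explicit normal equations; returns flagged indices."""
    t = np.asarray(days, dtype=float)
    w = np.asarray(weights, dtype=float)
    X = np.column_stack([np.ones_like(t), t, t * t])
    beta = np.linalg.solve(X.T @ X, X.T @ w)
    resid = w - X @ beta
    n = len(w)
    sd = np.sqrt(np.sum((resid - resid.mean()) ** 2) / (n - 1))
    return sorted(i for i in range(n)
                  if abs(resid[i]) > sd_mult * sd and abs(resid[i]) > abs_lb)


def oracle_rate_flags(days, weights, frac=0.02):
    """Consecutive-pair percent-per-day scan; returns flagged indices."""
    idx = np.argsort(np.asarray(days), kind="stable")
    d = np.asarray(days, dtype=float)[idx]
    w = np.asarray(weights, dtype=float)[idx]
    out = set()
    for i in range(len(d) - 1):
        if abs(w[i + 1] - w[i]) / (w[i] * (d[i + 1] - d[i])) > frac:
            out.update({idx[i], idx[i + 1]})
    return sorted(out)


def oracle_jump_flags(weights, threshold=50.0):
    """Exhaustive pairwise |diff| >= threshold scan; returns flagged indices."""
    w = np.asarray(weights, dtype=float)
    out = set()
    for i in range(len(w)):
        for j in range(i + 1, len(w)):
            if abs(w[j] - w[i]) >= threshold:
                out.update({i, j})
    return sorted(out)


def oracle_range_flag(weights, threshold=100.0):
    """Member-level max-min check; returns (flagged, argmin, argmax)."""
    w = np.asarray(weights, dtype=float)
    flagged = (len(w) >= 2) and (w.max() - w.min() >= threshold)
    return flagged, int(np.argmin(w)), int(np.argmax(w))


def oracle_ols(X, y):
    """Normal-equations least squares (intercept included by the caller)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)
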