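"""Call-rate inference: count tables, NB GLMM, contrasts, variance shares.

Counts per event x treatment x call type are modelled as

    count ~ treatment * call_type + offset(log exposure_min) + (1 | event)

with a negative-binomial response and log link.  The reference treatment is
``during``, so the before/after coefficients are directly the log
rate-ratios relative to the noisy period.  Six pairwise contrasts
(before-during and after-during within each call type) are tested with
two-sided normal p-values and a joint Holm step-down correction.  The
latent-scale variance decomposition (fixed / random / residual) follows the
marginal-conditional pseudo-R2 convention for log-link count models, with
the trigamma form of the distribution-specific residual variance.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .glmm import GLMMResult, NegativeBinomialMixedModel

__all__ = [
    "CallCountRecord",
    "ContrastResult",
    "ChiSquareResult",
    "RATE_CALL_TYPES",
    "tabulate_rates",
    "records_to_frame",
    "build_design",
    "fit_nb_glmm",
    "pairwise_contrasts",
    "holm_adjust",
    "pseudo_r2",
    "chisq_independence",
]

TREATMENTS = ("before", "during", "after")
#: call types entering the rate model; HFBP pools monophonic and biphonal
RATE_CALL_TYPES = ("CC", "HFBP", "OTHER")

_POOLING = {
    "HFBP_M": "HFBP",
    "HFBP_B": "HFBP",
    "HFBP": "HFBP",
    "CC": "CC",
    "OTHER": "OTHER",
    "WHISTLE": "OTHER",
}


@dataclass
class CallCountRecord:
    """Calls of one type counted in one treatment clip of one event."""

    event_id: str
    treatment: str
    call_type: str
    count: int
    exposure_min: float

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.call_type not in RATE_CALL_TYPES:
            raise ValueError(f"unknown call type {self.call_type!r}")
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.exposure_min <= 0:
            raise ValueError("exposure must be positive")


@dataclass
class ContrastResult:
    """One treatment contrast within a call type."""

    label: str
    estimate: float
    se: float
    z: float
    p_raw: float
    p_holm: float


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float


def tabulate_rates(
    classified: Iterable[tuple[str, str, str]],
    durations_s: dict,
) -> list[CallCountRecord]:
    """Count classified selections into event x treatment x type records.

    ``classified`` yields (event_id, treatment, class_label) per selection;
    buzzes flagged BUZZ_EXCLUDED are dropped (they are not communication
    calls), HFBP_M/HFBP_B pool into HFBP, and whistles fall under OTHER.
    ``durations_s`` maps (event_id, treatment) to the analysed clip length
    in seconds; every event contributes all 9 cells, zero-filled.
    """
    counts: dict = {}
    events: list[str] = []
    for event_id, treatment, label in classified:
        if label == "BUZZ_EXCLUDED":
            continue
        if treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {treatment!r}")
        pooled = _POOLING.get(label)
        if pooled is None:
            raise ValueError(f"unknown call class {label!r}")
        if event_id not in events:
            events.append(event_id)
        counts[(event_id, treatment, pooled)] = counts.get((event_id, treatment, pooled), 0) + 1
    for (event_id, treatment) in durations_s:
        if event_id not in events:
            events.append(event_id)
    records = []
    for event_id in events:
        for treatment in TREATMENTS:
            key = (event_id, treatment)
            if key not in durations_s:
                raise ValueError(f"missing duration for event {event_id!r} treatment {treatment!r}")
            exposure = durations_s[key] / 60.0
            for call_type in RATE_CALL_TYPES:
                records.append(
                    CallCountRecord(
                        event_id=event_id,
                        treatment=treatment,
                        call_type=call_type,
                        count=counts.get((event_id, treatment, call_type), 0),
                        exposure_min=exposure,
                    )
                )
    return records


def records_to_frame(records: Sequence[CallCountRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": [r.event_id for r in records],
            "treatment": [r.treatment for r in records],
            "call_type": [r.call_type for r in records],
            "count": [r.count for r in records],
            "exposure_min": [r.exposure_min for r in records],
        }
    )


def build_design(frame: pd.DataFrame) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Treatment x call-type interaction design with reference (during, CC).

    Returns (X, column names, y, offset = log exposure_min, group indices).
    """
    t_before = (frame["treatment"] == "before").to_numpy(float)
    t_after = (frame["treatment"] == "after").to_numpy(float)
    c_hfbp = (frame["call_type"] == "HFBP").to_numpy(float)
    c_other = (frame["call_type"] == "OTHER").to_numpy(float)
    X = np.column_stack(
        [
            np.ones(len(frame)),
            t_before,
            t_after,
            c_hfbp,
            c_other,
            t_before * c_hfbp,
            t_before * c_other,
            t_after * c_hfbp,
            t_after * c_other,
        ]
    )
    names = [
        "intercept",
        "before",
        "after",
        "HFBP",
        "OTHER",
        "before:HFBP",
        "before:OTHER",
        "after:HFBP",
        "after:OTHER",
    ]
    y = frame["count"].to_numpy(float)
    offset = np.log(frame["exposure_min"].to_numpy(float))
    _, groups = np.unique(frame["event_id"].to_numpy(), return_inverse=True)
    return X, names, y, offset, groups


def fit_nb_glmm(records: Sequence[CallCountRecord], **model_kw) -> GLMMResult:
    """Fit the NB mixed rate model to count records."""
    frame = records_to_frame(records)
    if frame["event_id"].nunique() < 2:
        raise ValueError("need at least two events")
    X, names, y, offset, groups = build_design(frame)
    model = NegativeBinomialMixedModel(**model_kw)
    return model.fit(X, y, groups, offset=offset, names=names)


def holm_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (monotonicity enforced)."""
    return multipletests(np.asarray(p_raw, float), method="holm")[1]


#: contrast label -> coefficients on the design columns of build_design
_CONTRASTS = {
    "CC: before - during": {"before": 1.0},
    "CC: after - during": {"after": 1.0},
    "HFBP: before - during": {"before": 1.0, "before:HFBP": 1.0},
    "HFBP: after - during": {"after": 1.0, "after:HFBP": 1.0},
    "OTHER: before - during": {"before": 1.0, "before:OTHER": 1.0},
    "OTHER: after - during": {"after": 1.0, "after:OTHER": 1.0},
}


def pairwise_contrasts(fit: GLMMResult) -> list[ContrastResult]:
    """Six within-type treatment contrasts with joint Holm correction.

    Each contrast is a linear combination of fixed effects; its standard
    error comes from the fixed-effect covariance, the p-value from a
    two-sided normal test, and the six p-values are adjusted as one family.
    """
    if not fit.converged:
        raise ValueError("model did not converge; contrasts are unreliable")
    idx = {n: i for i, n in enumerate(fit.names)}
    rows = []
    for label, combo in _CONTRASTS.items():
        L = np.zeros(len(fit.names))
        for name, w in combo.items():
            L[idx[name]] = w
        est = float(L @ fit.beta)
        var = float(L @ fit.cov_beta @ L)
        if var <= 0:
            raise ValueError("singular fixed-effect covariance")
        se = np.sqrt(var)
        z = est / se
        rows.append((label, est, se, z, 2.0 * stats.norm.sf(abs(z))))
    p_holm = holm_adjust(np.array([r[4] for r in rows]))
    return [
        ContrastResult(label=r[0], estimate=r[1], se=r[2], z=r[3], p_raw=r[4], p_holm=float(ph))
        for r, ph in zip(rows, p_holm)
    ]


def pseudo_r2(fit: GLMMResult) -> tuple[float, float, float]:
    """Latent-scale variance shares (fixed, random, residual), in percent.

    sigma2_f is the variance of the fixed-effect linear predictor over the
    data, sigma2_a the random-intercept variance, and the residual is the
    NB distribution-specific variance on the log scale in its trigamma
    form, psi1(1 / (1/lambda + 1/theta)), with lambda the model's marginal
    mean count.  The three shares sum to 100.
    """
    eta_fixed = fit.X @ fit.beta
    var_f = float(np.var(eta_fixed))
    var_a = float(fit.sigma2_event)
    lam = float(np.exp(np.mean(eta_fixed + fit.offset) + var_a / 2.0))
    var_e = float(special.polygamma(1, 1.0 / (1.0 / lam + 1.0 / fit.theta)))
    total = var_f + var_a + var_e
    if total <= 0:
        raise ValueError("zero total latent variance")
    marginal = 100.0 * var_f / total
    random_share = 100.0 * var_a / total
    return marginal, random_share, 100.0 - marginal - random_share


def chisq_independence(table: np.ndarray) -> ChiSquareResult:
    """Pearson chi-square test of independence on an r x c count table."""
    table = np.asarray(table, dtype=np.float64)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) <= 0) or np.any(table.sum(axis=1) <= 0):
        raise ValueError("all row and column margins must be positive")
    statistic, p, df, _ = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(statistic=float(statistic), df=int(df), p=float(p))
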