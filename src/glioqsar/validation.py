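"""External and internal QSAR validation statistics.

Implements the external predictive R² (referenced to the training-set
activity mean), the rm² family (penalizing divergence between the ordinary
and the through-origin correlation of predictions vs observations), and
Y-randomization (response scrambling) summarized by R²p.  The rm² and R²p
formulas follow their standard forms in the QSAR validation literature:

    rm²  = r² · (1 − sqrt(r² − r0²))          (radicand clamped at 0)
    R²p  = r² · sqrt(r² − mean(r²_scrambled)) (radicand clamped at 0)

with r0² the through-origin analogue of r².  Because the direction of the
through-origin fit is a genuine convention choice, both the direct
(predictions on observations) and reversed variants are computed and their
mean is reported as the "overall" rm².  All three statistics pass when they
exceed 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np


@dataclass(frozen=True)
class ExternalValidationInput:
    """Observed/predicted test-set activities plus the training mean."""

    y_test: np.ndarray
    yhat_test: np.ndarray
    ybar_train: float

    def __post_init__(self) -> None:
        y = np.asarray(self.y_test, dtype=float)
        yh = np.asarray(self.yhat_test, dtype=float)
        if y.shape != yh.shape or y.ndim != 1:
            raise ValueError("y_test and yhat_test must be equal-length vectors")
        if len(y) < 2:
            raise ValueError("need at least 2 test compounds")
        object.__setattr__(self, "y_test", y)
        object.__setattr__(self, "yhat_test", yh)

    @property
    def n_test(self) -> int:
        return len(self.y_test)


def r2_ext(inp: ExternalValidationInput) -> float:
    """External predictive R²:

        R²ext = 1 − Σ(yi − ŷi)² / Σ(yi − ȳ_train)²

    May be negative (predictions worse than the training mean).  Errors if
    the test activities all equal the training mean (zero denominator).
    """
    y, yh = inp.y_test, inp.yhat_test
    denom = float(np.sum((y - inp.ybar_train) ** 2))
    if denom <= 0:
        raise ValueError(
            "test activities all equal the training mean; R2ext undefined"
        )
    return 1.0 - float(np.sum((y - yh) ** 2)) / denom


def _pearson_r2(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() <= 0 or b.std() <= 0:
        raise ValueError("constant input: correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


def _r0_squared(target: np.ndarray, regressor: np.ndarray) -> float:
    """Squared correlation of a least-squares fit *through the origin* of
    ``target`` on ``regressor``: 1 − Σ(t − k·x)²/Σ(t − t̄)²."""
    k = float(np.dot(target, regressor) / np.dot(regressor, regressor))
    rss = float(np.sum((target - k * regressor) ** 2))
    tss = float(np.sum((target - target.mean()) ** 2))
    if tss <= 0:
        raise ValueError("constant input: r0^2 undefined")
    return 1.0 - rss / tss


def rm2(y: Sequence[float], yhat: Sequence[float]) -> tuple[float, float, float]:
    """The rm² metric and its reversed and overall variants.

    rm² = r²·(1 − sqrt(r² − r0²)) with r0² from the through-origin fit of
    predictions on observations; the reversed variant swaps the roles; the
    overall value is the mean of the two.  Radicands are clamped at 0.
    """
    y = np.asarray(y, dtype=float)
    yh = np.asarray(yhat, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 points")
    r2 = _pearson_r2(y, yh)
    r0_direct = _r0_squared(yh, y)  # predictions through origin on observations
    r0_rev = _r0_squared(y, yh)
    rm = r2 * (1.0 - np.sqrt(max(0.0, r2 - r0_direct)))
    rm_rev = r2 * (1.0 - np.sqrt(max(0.0, r2 - r0_rev)))
    return float(rm), float(rm_rev), float((rm + rm_rev) / 2.0)


def y_randomization(
    fit_fn: Callable[[np.ndarray, np.ndarray], float],
    X: np.ndarray,
    y: np.ndarray,
    n_iter: int = 20,
    seed: int = 0,
) -> tuple[float, list[float]]:
    """Response scrambling: permute y ``n_iter`` times, refit, and collect
    the scrambled models' R²r values.

        R²p = r² · sqrt(r² − mean(R²r)),  radicand clamped at 0.

    ``fit_fn(X, y)`` must deterministically return the fitted model's R²
    (a float, or an object with an ``r2`` attribute / ``stats['r2']``).
    Scrambled fits that raise are excluded with a warning (the effective
    iteration count is len of the returned list).
    """
    import warnings

    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)

    def extract(res) -> float:
        if isinstance(res, (int, float, np.floating)):
            return float(res)
        if hasattr(res, "r2"):
            return float(res.r2)
        if hasattr(res, "stats"):
            return float(res.stats["r2"])
        raise TypeError("fit_fn must return a float r2 or model exposing one")

    r2_orig = extract(fit_fn(X, y))
    rng = np.random.default_rng(seed)
    r2_r: list[float] = []
    failures = 0
    for _ in range(n_iter):
        perm = rng.permutation(len(y))
        try:
            r2_r.append(extract(fit_fn(X, y[perm])))
        except Exception as exc:  # noqa: BLE001 - scrambles may be degenerate
            failures += 1
            warnings.warn(f"scrambled fit failed ({exc}); excluded", stacklevel=2)
    if not r2_r:
        raise RuntimeError("every scrambled fit failed")
    if failures:
        warnings.warn(
            f"{failures}/{n_iter} scrambled fits excluded; effective n_iter="
            f"{len(r2_r)}",
            stacklevel=2,
        )
    r2p = r2_orig * float(np.sqrt(max(0.0, r2_orig - float(np.mean(r2_r)))))
    return float(r2p), r2_r


@dataclass
class ValidationReport:
    """Bundle of the external/internal validation statistics."""

    r2_ext: float
    r2: float
    r0_2: float
    r0_2_reversed: float
    rm2: float
    rm2_reversed: float
    rm2_overall: float
    r2_p: float | None = None
    r2_r_list: list[float] = field(default_factory=list)

    def passes(self, threshold: float = 0.5) -> dict[str, bool]:
        out = {
            "r2_ext": self.r2_ext > threshold,
            "rm2_overall": self.rm2_overall > threshold,
        }
        if self.r2_p is not None:
            out["r2_p"] = self.r2_p > threshold
        return out


def validate_external(
    y_test: Sequence[float],
    yhat_test: Sequence[float],
    ybar_train: float,
) -> ValidationReport:
    """Convenience: compute R²ext, r², both r0² conventions, and the rm²
    family for one test set."""
    inp = ExternalValidationInput(
        y_test=np.asarray(y_test, float),
        yhat_test=np.asarray(yhat_test, float),
        ybar_train=float(ybar_train),
    )
    y, yh = inp.y_test, inp.yhat_test
    rm, rm_rev, rm_all = rm2(y, yh)
    return ValidationReport(
        r2_ext=r2_ext(inp),
        r2=_pearson_r2(y, yh),
        r0_2=_r0_squared(yh, y),
        r0_2_reversed=_r0_squared(y, yh),
        rm2=rm,
        rm2_reversed=rm_rev,
        rm2_overall=rm_all,
    )


#: Published validation statistics for the dihydropteridone CoMSIA model,
#: carried as metadata (they depend on the commercial field model).
PUBLISHED_VALIDATION_STATS = {"r2_ext": 0.65, "rm2": 0.64, "r2_p": 0.61}
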