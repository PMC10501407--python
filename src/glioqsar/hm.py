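"""Heuristic forward descriptor selection and multilinear QSAR fitting.

The heuristic method (HM) screens a large candidate descriptor pool
(hundreds of quantum-chemical/topological/geometric descriptors for a few
dozen compounds), removes degenerate and mutually collinear columns, and
grows a multilinear model one descriptor at a time, scoring each candidate
subset by R², leave-one-out R²cv, s², F and per-coefficient t statistics.
The module also carries the published six-descriptor dihydropteridone model
as a verbatim reference evaluator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from glioqsar.datasets import DESCRIPTOR_REGISTRY, DescriptorTable


@dataclass
class LinearQsarModel:
    """Intercept + named coefficients + fit statistics.

    ``stats_source`` distinguishes models fitted by this package ("fitted")
    from published reference models whose statistics are carried as metadata
    ("published") rather than recomputed.
    """

    intercept: float
    terms: dict[str, float]
    stats: dict = field(default_factory=dict)
    stats_source: str = "fitted"

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate term names")
        r2 = self.stats.get("r2")
        if r2 is not None and not (-1e-9 <= r2 <= 1 + 1e-9):
            raise ValueError(f"r2 out of [0,1]: {r2}")

    @property
    def names(self) -> list[str]:
        return list(self.terms)

    def predict(self, x: Mapping[str, float]) -> float:
        return evaluate_linear(self, x)

    def predict_table(self, table: DescriptorTable) -> np.ndarray:
        X = table.select(self.names).values
        beta = np.array([self.terms[n] for n in self.names])
        return self.intercept + X @ beta

    def to_yaml(self, path: str | Path | None = None) -> str:
        payload = {
            "model": "linear_qsar",
            "intercept": self.intercept,
            "terms": dict(self.terms),
            "stats": dict(self.stats),
            "stats_source": self.stats_source,
        }
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, text_or_path: str | Path) -> "LinearQsarModel":
        p = Path(str(text_or_path))
        text = p.read_text(encoding="utf-8") if p.exists() else str(text_or_path)
        d = yaml.safe_load(text)
        return cls(
            intercept=d["intercept"],
            terms=dict(d["terms"]),
            stats=dict(d.get("stats", {})),
            stats_source=d.get("stats_source", "fitted"),
        )


@dataclass
class SelectionStep:
    k: int
    names: list[str]
    r2: float
    r2_cv: float
    s2: float


@dataclass
class SelectionTrace:
    """Per-size record of the greedy forward search (nested subsets)."""

    steps: list[SelectionStep]
    recommended_size: int
    stop_delta: float

    @property
    def recommended_names(self) -> list[str]:
        for s in self.steps:
            if s.k == self.recommended_size:
                return s.names
        raise ValueError("recommended size not in trace")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "k": [s.k for s in self.steps],
                "descriptors": ["+".join(s.names) for s in self.steps],
                "r2": [s.r2 for s in self.steps],
                "r2_cv": [s.r2_cv for s in self.steps],
                "s2": [s.s2 for s in self.steps],
            }
        )


def evaluate_linear(model: LinearQsarModel, x: Mapping[str, float]) -> float:
    """Evaluate ``intercept + sum(coef * x[name])``.

    Missing descriptor names are an error (listed); extra names are ignored
    with a warning.  Output is independent of the ordering of ``x``.
    """
    missing = [n for n in model.terms if n not in x]
    if missing:
        raise KeyError(f"missing descriptor values for: {missing}")
    extra = [n for n in x if n not in model.terms]
    if extra:
        warnings.warn(f"ignoring descriptors not in model: {extra}", stacklevel=2)
    return model.intercept + sum(c * float(x[n]) for n, c in model.terms.items())


def reference_hm_model() -> LinearQsarModel:
    """The published six-descriptor linear model, verbatim.

    pAct = -24.280 + 0.29798·NFA + 0.44403·MRCH + 5.6298·MECN
           - 0.57965·TEIZP + 3.6953·ZXS - 3.8370·MCIHN

    Its statistics (R² 0.6682, R²cv 0.5669, s² 0.0199, on the 26-compound
    training split) are carried as published metadata, not recomputed: the
    commercial descriptor matrix behind them is not available.
    """
    terms = {name: e.coefficient for name, e in DESCRIPTOR_REGISTRY.items()}
    t_values = {name: e.t_value for name, e in DESCRIPTOR_REGISTRY.items()}
    return LinearQsarModel(
        intercept=-24.280,
        terms=terms,
        stats={"r2": 0.6682, "r2_cv": 0.5669, "s2": 0.0199, "t_values": t_values},
        stats_source="published",
    )


def _design_matrix(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    return np.column_stack([np.ones(n), X])


def fit_mlr(
    X: np.ndarray | DescriptorTable,
    y: np.ndarray,
    names: Sequence[str] | None = None,
) -> LinearQsarModel:
    """Ordinary least squares fit with LOO cross-validation diagnostics.

    Returns a model with R², leave-one-out R²cv (hat-matrix shortcut),
    s² = RSS/(n-k-1), overall F, and per-coefficient t values.  ``X`` must be
    full column rank and ``n > k + 1``.  A zero-variance response yields
    r2 = 0 by convention.
    """
    if isinstance(X, DescriptorTable):
        names = X.descriptor_names
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if names is None:
        names = [f"x{i}" for i in range(k)]
    if n <= k + 1:
        raise ValueError(f"need n > k+1 samples (n={n}, k={k})")
    D = _design_matrix(X)
    rank = np.linalg.matrix_rank(D)
    if rank < k + 1:
        # name the offending columns by checking rank growth
        dep = []
        cols = [np.ones(n)]
        for j, nm in enumerate(names):
            trial = np.column_stack(cols + [X[:, j]])
            if np.linalg.matrix_rank(trial) == len(cols):
                dep.append(nm)
            else:
                cols.append(X[:, j])
        raise ValueError(f"design matrix rank deficient; dependent columns: {dep}")

    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    yhat = D @ beta
    resid = y - yhat
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0:
        r2 = 0.0  # degenerate constant response
        r2_cv = 0.0
    else:
        r2 = 1.0 - rss / tss
        # LOO via hat matrix: e_loo_i = e_i / (1 - h_ii)
        G = np.linalg.inv(D.T @ D)
        h = np.einsum("ij,jk,ik->i", D, G, D)
        loo_resid = resid / (1.0 - h)
        press = float(loo_resid @ loo_resid)
        r2_cv = 1.0 - press / tss
    dof = n - k - 1
    s2 = rss / dof
    G = np.linalg.inv(D.T @ D)
    se = np.sqrt(np.clip(np.diag(G) * s2, 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_all = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    f_value = (r2 / k) / ((1.0 - r2) / dof) if r2 < 1.0 else np.inf
    return LinearQsarModel(
        intercept=float(beta[0]),
        terms={nm: float(b) for nm, b in zip(names, beta[1:])},
        stats={
            "r2": float(min(r2, 1.0)),
            "r2_cv": float(r2_cv),
            "s2": float(s2),
            "rss": rss,
            "f_value": float(f_value),
            "n": n,
            "t_values": {nm: float(t) for nm, t in zip(names, t_all[1:])},
            "t_intercept": float(t_all[0]),
        },
    )


def prefilter_descriptors(
    table: DescriptorTable,
    y: np.ndarray,
    collinearity_cap: float = 0.80,
    report: dict | None = None,
) -> DescriptorTable:
    """Drop constant columns and break collinear pairs.

    For any descriptor pair with ``|r| >= collinearity_cap`` the member less
    correlated (in absolute value) with the response is dropped.  ``report``,
    if supplied, is filled with ``name -> reason`` for every dropped column.
    Raises if nothing survives.
    """
    y = np.asarray(y, dtype=float)
    dropped: dict[str, str] = {}
    V = table.values
    names = table.descriptor_names
    sd = V.std(axis=0)
    keep = []
    for j, nm in enumerate(names):
        if sd[j] <= 1e-12:
            dropped[nm] = "constant column"
        else:
            keep.append(j)
    if keep:
        Vk = V[:, keep]
        kn = [names[j] for j in keep]
        # correlations with y
        yc = (y - y.mean())
        ysd = y.std()
        if ysd <= 0:
            ry = np.zeros(len(keep))
        else:
            ry = (Vk - Vk.mean(axis=0)).T @ yc / (len(y) * Vk.std(axis=0) * ysd)
        C = np.corrcoef(Vk, rowvar=False)
        if C.ndim == 0:
            C = np.array([[1.0]])
        alive = dict.fromkeys(range(len(kn)), True)
        # visit pairs in deterministic order; drop the weaker member
        pairs = [
            (i, j)
            for i in range(len(kn))
            for j in range(i + 1, len(kn))
            if abs(C[i, j]) >= collinearity_cap
        ]
        # strongest collinearity first so duplicates resolve predictably
        pairs.sort(key=lambda ij: (-abs(C[ij[0], ij[1]]), kn[ij[0]], kn[ij[1]]))
        for i, j in pairs:
            if not (alive[i] and alive[j]):
                continue
            # keep the one more correlated with y; ties keep lexicographically
            # smaller name
            wi, wj = abs(ry[i]), abs(ry[j])
            if (wi, kn[j]) >= (wj, kn[i]):
                loser = j
            else:
                loser = i
            alive[loser] = False
            winner = i if loser == j else j
            dropped[kn[loser]] = (
                f"|r|={abs(C[i, j]):.3f} with {kn[winner]} >= cap "
                f"{collinearity_cap}"
            )
        survivors = [kn[i] for i in range(len(kn)) if alive[i]]
    else:
        survivors = []
    if report is not None:
        report.update(dropped)
    if not survivors:
        raise ValueError("prefilter dropped every descriptor column")
    return table.select(survivors)


def heuristic_select(
    table: DescriptorTable,
    y: np.ndarray,
    k_max: int = 8,
    stop_delta: float = 0.02,
    collinearity_cap: float = 0.80,
) -> SelectionTrace:
    """Greedy forward selection maximizing R² at each subset size.

    At each step the candidate whose addition gives the largest R² is chosen
    among descriptors whose pairwise |r| with every already-selected
    descriptor stays below ``collinearity_cap``; ties break to the
    lexicographically smaller name.  The recommended size is the largest k
    whose R² improvement over k-1 is at least ``stop_delta`` (descriptors
    beyond the plateau add nothing).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k_max >= n - 2:
        raise ValueError(f"k_max must be < n-2 (n={n}, k_max={k_max})")
    names = table.descriptor_names
    V = table.frame
    C = np.corrcoef(table.values, rowvar=False)
    idx = {nm: j for j, nm in enumerate(names)}

    selected: list[str] = []
    steps: list[SelectionStep] = []
    for k in range(1, k_max + 1):
        best = None  # (r2, name, model)
        for nm in names:
            if nm in selected:
                continue
            if any(abs(C[idx[nm], idx[s]]) >= collinearity_cap for s in selected):
                continue
            trial = selected + [nm]
            try:
                m = fit_mlr(V[trial].to_numpy(), y, trial)
            except (ValueError, np.linalg.LinAlgError):
                continue
            r2 = m.stats["r2"]
            # strictly larger r2 wins; equal r2 -> lexicographically smaller name
            if best is None or r2 > best[0] or (r2 == best[0] and nm < best[1]):
                best = (r2, nm, m)
        if best is None:
            break
        selected = selected + [best[1]]
        m = best[2]
        steps.append(
            SelectionStep(
                k=k,
                names=list(selected),
                r2=m.stats["r2"],
                r2_cv=m.stats["r2_cv"],
                s2=m.stats["s2"],
            )
        )
    if not steps:
        raise ValueError("forward selection found no admissible descriptor")
    rec = steps[0].k
    prev = 0.0
    for s in steps:
        if s.r2 - prev >= stop_delta:
            rec = s.k
        prev = s.r2
    return SelectionTrace(steps=steps, recommended_size=rec, stop_delta=stop_delta)
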