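"""Synthetic inputs with the statistical structure the QSAR analysis assumes.

Real descriptor matrices for this compound class come from commercial
quantum-chemistry engines and are not redistributable; the generators here
produce inputs with the same *shape* of difficulty — a few dozen compounds,
hundreds of candidate descriptors with block collinearity, a small planted
descriptor subset driving activity linearly or through a known nonlinear
expression, and pseudo-aligned molecules whose Gaussian field columns drive
activity through a planted coefficient vector.  Every generator is a pure
function of its spec (seed included), and noiseless plants are exactly
recoverable by the matching downstream fitter, which is what makes the
whole pipeline testable with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from glioqsar.comsia import (
    BONDI_RADII,
    DEFAULT_MARGIN,
    DEFAULT_MIN_SIGMA,
    DEFAULT_SPACING,
    AlignedMolecule,
    FieldGrid,
    FieldMatrix,
    assemble_field_matrix,
    build_grid,
)
from glioqsar.datasets import DESCRIPTOR_REGISTRY, DescriptorTable
from glioqsar.gep import ExpressionTree, evaluate_tree_rows


@dataclass(frozen=True)
class LinearPlantSpec:
    """Planted linear descriptor–activity relationship.

    ``collinearity_blocks`` lists (size, within-block correlation) pairs;
    blocks occupy consecutive filler columns after the true subset, so the
    planted signal stays identifiable.  Columns are empirically standardized.
    """

    n_compounds: int = 34
    n_descriptors: int = 500
    true_subset: tuple[str, ...] = ()
    true_coefficients: tuple[float, ...] = ()  # per true_subset name
    intercept: float = 0.0
    noise_sd: float = 0.0
    collinearity_blocks: tuple[tuple[int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.true_coefficients) != len(self.true_subset):
            raise ValueError(
                "true_coefficients must have one entry per true_subset name"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        k = len(self.true_subset)
        nblk = sum(size for size, _ in self.collinearity_blocks)
        if k + nblk > self.n_descriptors:
            raise ValueError("true subset + collinearity blocks exceed p")
        for size, r in self.collinearity_blocks:
            if size < 2:
                raise ValueError("collinearity block size must be >= 2")
            # equicorrelated block PSD requires r >= -1/(size-1)
            if not (-1.0 / (size - 1) < r < 1.0 + 1e-12):
                raise ValueError(
                    f"block correlation {r} not positive semi-definite for "
                    f"size {size}"
                )


@dataclass(frozen=True)
class NonlinearPlantSpec:
    """Planted nonlinear relationship: y = expression(descriptors) + noise."""

    expression: ExpressionTree
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_descriptor_matrix(spec: LinearPlantSpec) -> DescriptorTable:
    """Standard-normal descriptor matrix with the requested block
    collinearity, deterministically seeded and empirically standardized.

    Column order: true-subset names first, then filler names D0001…; the
    collinearity blocks cover consecutive filler columns immediately after
    the true subset.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_compounds, spec.n_descriptors
    if n < 4:
        raise ValueError("need at least 4 compounds")
    k = len(spec.true_subset)
    names = list(spec.true_subset) + [
        f"D{i:04d}" for i in range(1, p - k + 1)
    ]
    Z = rng.standard_normal((n, p))
    X = Z.copy()
    col = k
    for size, r in spec.collinearity_blocks:
        # equicorrelated block via Cholesky of (1-r) I + r 11'
        C = np.full((size, size), r)
        np.fill_diagonal(C, 1.0)
        L = np.linalg.cholesky(C)
        X[:, col : col + size] = Z[:, col : col + size] @ L.T
        col += size
    sd = X.std(axis=0)
    sd[sd <= 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    return DescriptorTable(pd.DataFrame(X, columns=names,
                                        index=[f"cpd{i + 1:03d}" for i in range(n)]))


@dataclass
class ActivityResult:
    """Generated activity with the noiseless ground truth alongside."""

    y: np.ndarray
    y_true: np.ndarray
    flagged_rows: list[int] = field(default_factory=list)


def generate_activity(
    table: DescriptorTable,
    plant: LinearPlantSpec | NonlinearPlantSpec,
) -> ActivityResult:
    """y = f(true descriptors) + N(0, noise_sd); the noiseless vector is
    returned for oracle tests.  Rows where a nonlinear expression is
    undefined (e.g. division blow-up) are reported in ``flagged_rows``."""
    cols = {nm: table.column(nm) for nm in table.descriptor_names}
    if isinstance(plant, LinearPlantSpec):
        missing = [nm for nm in plant.true_subset if nm not in cols]
        if missing:
            raise KeyError(f"plant references absent descriptors: {missing}")
        y_true = np.full(table.shape[0], plant.intercept, dtype=float)
        for nm, c in zip(plant.true_subset, plant.true_coefficients):
            y_true = y_true + c * cols[nm]
    else:
        missing = [t for t in plant.expression.terminals() if t not in cols]
        if missing:
            raise KeyError(f"expression references absent descriptors: {missing}")
        y_true = evaluate_tree_rows(plant.expression, cols)
    flagged = np.where(~np.isfinite(y_true))[0].tolist()
    rng = np.random.default_rng(plant.seed + 1)  # distinct stream from X
    noise = rng.normal(0.0, plant.noise_sd, size=len(y_true)) if plant.noise_sd else 0.0
    return ActivityResult(y=y_true + noise, y_true=y_true, flagged_rows=flagged)


# -- emulation preset -------------------------------------------------------

#: activity range of the packaged compound table on the pAct scale
PRESET_ACTIVITY_RANGE = (8.97, 9.74)
PRESET_TRUE_R2 = 0.67


def paper_preset(seed: int = 0) -> tuple[DescriptorTable, ActivityResult, LinearPlantSpec]:
    """The default emulation regime: 34 compounds, 500 candidate
    descriptors, a 6-descriptor truth with coefficient magnitudes
    proportional to the published linear model's, three collinear filler
    blocks of 5 at r = 0.9, noise set so the true model's R² ≈ 0.67, and
    activities affinely mapped onto the packaged table's pAct span
    [8.97, 9.74]."""
    names = tuple(DESCRIPTOR_REGISTRY)
    raw = np.array([DESCRIPTOR_REGISTRY[n].coefficient for n in names])
    coefs = raw / np.abs(raw).max()  # proportional magnitudes, order preserved
    spec = LinearPlantSpec(
        n_compounds=34,
        n_descriptors=500,
        true_subset=names,
        true_coefficients=tuple(coefs),
        intercept=0.0,
        noise_sd=0.0,  # filled below from the signal variance
        collinearity_blocks=((5, 0.9), (5, 0.9), (5, 0.9)),
        seed=seed,
    )
    table = generate_descriptor_matrix(spec)
    base = generate_activity(table, spec)
    sig_sd = float(base.y_true.std())
    noise_sd = sig_sd * np.sqrt((1 - PRESET_TRUE_R2) / PRESET_TRUE_R2)
    spec = LinearPlantSpec(
        n_compounds=spec.n_compounds,
        n_descriptors=spec.n_descriptors,
        true_subset=spec.true_subset,
        true_coefficients=spec.true_coefficients,
        intercept=spec.intercept,
        noise_sd=noise_sd,
        collinearity_blocks=spec.collinearity_blocks,
        seed=seed,
    )
    res = generate_activity(table, spec)
    # affine map of the noiseless span onto the pAct range; same map applied
    # to the noisy vector so R² is unchanged
    lo, hi = PRESET_ACTIVITY_RANGE
    t_lo, t_hi = float(res.y_true.min()), float(res.y_true.max())
    slope = (hi - lo) / (t_hi - t_lo)
    shift = lo - slope * t_lo
    res = ActivityResult(
        y=slope * res.y + shift,
        y_true=slope * res.y_true + shift,
        flagged_rows=res.flagged_rows,
    )
    return table, res, spec


# -- 3D field plant ---------------------------------------------------------

#: default per-atom property ranges for decoration atoms
DEFAULT_PROPERTY_RANGES: Mapping[str, tuple[float, float]] = {
    "charge": (-0.5, 0.5),
    "hydrophobicity": (-1.0, 1.0),
}

_SCAFFOLD_ELEMENTS = ("C", "N", "O")
_SCAFFOLD_COORDS = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.0, 1.5, 0.0]])
_DECORATION_ELEMENTS = ("C", "N", "O", "F", "S")
_DECORATION_BOX = 3.0  # decorations land in [-box, +box]^3, Å


@dataclass(frozen=True)
class FieldPlantSpec:
    """Planted field–activity structure for the 3D branch.

    Molecules share a fixed 3-atom scaffold (pre-aligned by construction)
    plus randomized decoration atoms; activity is a linear combination of
    (grid point × field) similarity columns plus noise.

    The planted coefficient pattern is chosen by ``plant``:

    * ``"blobs"`` (default): smooth localized Gaussian blobs over grid
      points of the fields in ``blob_fields`` (hydrophobic-favored plus a
      steric-disfavored region, echoing the dominant real-data fields),
      projected onto the span of contrasts the generated field matrix can
      actually realize — a coefficient component orthogonal to that span is
      statistically invisible to any fitter, so planting it would make the
      ground truth unrecoverable by construction.
    * ``"spikes"``: ``n_active_weights`` isolated high-contrast columns
      with independent normal weights (a deliberately hard, largely
      unidentifiable target; useful for stress tests).

    An explicit ``planted_weights`` mapping (flat field-matrix column index
    -> weight) overrides both.  ``noise_fraction``, when set, scales the
    noise to that fraction of the noiseless activity's standard deviation
    (otherwise ``noise_sd`` is absolute).
    """

    n_molecules: int = 50
    atoms_per_molecule: tuple[int, int] = (4, 10)  # decoration atoms, inclusive
    property_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PROPERTY_RANGES)
    )
    planted_weights: Mapping[int, float] | None = None
    plant: str = "blobs"
    blob_fields: tuple[tuple[str, float], ...] = (("H", 1.0), ("S", -0.7))
    blob_sigma: float = 2.0  # Å
    n_active_weights: int = 12
    weight_scale: float = 1.0
    noise_sd: float = 0.0
    noise_fraction: float | None = None
    spacing: float = DEFAULT_SPACING
    margin: float = DEFAULT_MARGIN
    min_sigma: float = DEFAULT_MIN_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.atoms_per_molecule
        if lo < 1 or hi < lo:
            raise ValueError("atoms_per_molecule must be a valid range >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.plant not in ("blobs", "spikes"):
            raise ValueError("plant must be 'blobs' or 'spikes'")
        if self.noise_fraction is not None and self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")


@dataclass
class FieldPlantResult:
    molecules: list[AlignedMolecule]
    y: np.ndarray
    y_true: np.ndarray
    grid: FieldGrid
    field_matrix: FieldMatrix
    planted_weights: np.ndarray  # dense over all field-matrix columns


def generate_aligned_molecules(spec: FieldPlantSpec) -> FieldPlantResult:
    """Generate pseudo-aligned molecules and a planted field-driven
    activity, bit-identical per seed."""
    rng = np.random.default_rng(spec.seed)
    ch_lo, ch_hi = spec.property_ranges.get("charge", DEFAULT_PROPERTY_RANGES["charge"])
    hy_lo, hy_hi = spec.property_ranges.get(
        "hydrophobicity", DEFAULT_PROPERTY_RANGES["hydrophobicity"]
    )
    mols: list[AlignedMolecule] = []
    a_lo, a_hi = spec.atoms_per_molecule
    for i in range(spec.n_molecules):
        n_dec = int(rng.integers(a_lo, a_hi + 1))
        elements = list(_SCAFFOLD_ELEMENTS) + [
            _DECORATION_ELEMENTS[rng.integers(len(_DECORATION_ELEMENTS))]
            for _ in range(n_dec)
        ]
        coords = np.vstack(
            [_SCAFFOLD_COORDS,
             rng.uniform(-_DECORATION_BOX, _DECORATION_BOX, size=(n_dec, 3))]
        )
        n = len(elements)
        mols.append(
            AlignedMolecule(
                id=f"syn{i + 1:03d}",
                elements=elements,
                coords=coords,
                charges=rng.uniform(ch_lo, ch_hi, size=n),
                radii=np.array([BONDI_RADII.get(e, 1.7) for e in elements]),
                hydrophobicity=rng.uniform(hy_lo, hy_hi, size=n),
                donor=rng.random(n) < 0.3,
                acceptor=rng.random(n) < 0.3,
                scaffold_map=[0, 1, 2],
            )
        )
    grid = build_grid(mols, spacing=spec.spacing, margin=spec.margin)
    fm = assemble_field_matrix(mols, grid, min_sigma=spec.min_sigma)
    w = np.zeros(fm.values.shape[1])
    if spec.planted_weights is not None:
        for col, wt in spec.planted_weights.items():
            if not 0 <= col < len(w):
                raise ValueError(f"planted weight column {col} outside grid")
            w[col] = wt
    elif spec.plant == "spikes":
        eligible = np.where(fm.active_mask)[0]
        if len(eligible) < spec.n_active_weights:
            raise ValueError("not enough high-contrast columns to plant weights")
        chosen = rng.choice(eligible, size=spec.n_active_weights, replace=False)
        w[chosen] = rng.normal(0.0, spec.weight_scale, size=spec.n_active_weights)
    else:  # smooth localized blobs, projected onto the realizable span
        pts = grid.points()
        npts = grid.n_points
        for label, amp in spec.blob_fields:
            fi = fm.field_labels.index(label)
            center = rng.uniform(-_DECORATION_BOX * 2 / 3, _DECORATION_BOX * 2 / 3, 3)
            blob = amp * spec.weight_scale * np.exp(
                -np.sum((pts - center) ** 2, axis=1) / (2.0 * spec.blob_sigma**2)
            )
            w[fi * npts : (fi + 1) * npts] = blob
        act = fm.active_mask
        Xc = fm.active_values - fm.active_values.mean(axis=0)
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        keep = s > 1e-10 * s[0]
        w_act = Vt[keep].T @ (Vt[keep] @ w[act])
        w = np.zeros_like(w)
        w[act] = w_act
    y_true = fm.values @ w
    sd_noise = spec.noise_sd
    if spec.noise_fraction is not None:
        sd_noise = spec.noise_fraction * float(np.std(y_true))
    noise = rng.normal(0.0, sd_noise, size=len(y_true)) if sd_noise else 0.0
    return FieldPlantResult(
        molecules=mols,
        y=y_true + noise,
        y_true=y_true,
        grid=grid,
        field_matrix=fm,
        planted_weights=w,
    )


def write_molecules_sdf(molecules: Sequence[AlignedMolecule], path) -> None:
    """Write pseudo-aligned molecules as a bond-less V2000 SDF (coordinates
    and elements; per-atom field properties go in a companion table via
    :func:`write_property_table`)."""
    lines: list[str] = []
    for m in molecules:
        lines += [m.id, "  glioqsar          3D", ""]
        lines.append(f"{m.n_atoms:3d}{0:3d}  0  0  0  0  0  0  0  0999 V2000")
        for e, (x, y, z) in zip(m.elements, m.coords):
            lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {e:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
        lines += ["M  END", "$$$$"]
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_property_table(molecules: Sequence[AlignedMolecule], path) -> None:
    """Companion per-atom property table (delimited) for SDF round trips."""
    rows = []
    for m in molecules:
        for i in range(m.n_atoms):
            rows.append(
                {
                    "molecule": m.id,
                    "atom": i,
                    "element": m.elements[i],
                    "charge": m.charges[i],
                    "radius": m.radii[i],
                    "hydrophobicity": m.hydrophobicity[i],
                    "donor": int(m.donor[i]),
                    "acceptor": int(m.acceptor[i]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
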