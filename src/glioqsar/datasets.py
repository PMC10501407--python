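"""Compound activity tables, descriptor matrices, and dataset splitting.

The activity scale is pAct = 9 - log10(IC50/µM), so higher values mean more
potent inhibition.  The most potent compound in the packaged dihydropteridone
set (21E, IC50 = 0.18 µM) sits at pAct ≈ 9.74 and the least potent (13m,
1.07 µM) at ≈ 8.97.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

ROLES = ("train", "test", "validation", "unassigned")

_ACTIVITY_ATOL = 1e-9


def transform_activity(ic50: float, *, literal: bool = False) -> float:
    """Transform an IC50 in µM to the dimensionless log-activity scale.

    The default convention is ``pAct = 9 - log10(IC50/µM)``: potency grows as
    IC50 shrinks.  ``literal=True`` instead applies ``log10(IC50) + 9``
    (an alternate sign convention retained for audit runs; note it *increases*
    with IC50).

    Raises
    ------
    ValueError
        If ``ic50`` is non-positive or non-finite.
    """
    if not math.isfinite(ic50) or ic50 <= 0:
        raise ValueError(f"IC50 must be finite and > 0 (got {ic50!r})")
    if literal:
        return math.log10(ic50) + 9.0
    return 9.0 - math.log10(ic50)


def inverse_transform_activity(activity: float, *, literal: bool = False) -> float:
    """Map a transformed activity back to IC50 in µM."""
    if literal:
        return 10.0 ** (activity - 9.0)
    return 10.0 ** (9.0 - activity)


@dataclass
class CompoundRecord:
    """One compound: id, optional SMILES, IC50 (µM) and transformed activity."""

    id: str
    ic50: float | None = None
    smiles: str | None = None
    activity: float | None = None
    role: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("compound id must be non-empty")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.ic50 is not None:
            if not math.isfinite(self.ic50) or self.ic50 <= 0:
                raise ValueError(
                    f"compound {self.id!r}: IC50 must be finite and > 0 "
                    f"(got {self.ic50!r})"
                )
            if self.activity is None:
                self.activity = transform_activity(self.ic50)
            elif abs(self.activity - transform_activity(self.ic50)) > _ACTIVITY_ATOL:
                raise ValueError(
                    f"compound {self.id!r}: activity {self.activity} inconsistent "
                    f"with IC50 {self.ic50} µM "
                    f"(expected {transform_activity(self.ic50):.9f})"
                )


@dataclass
class CompoundSet:
    """Ordered collection of compounds with unique ids."""

    records: list[CompoundRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate compound ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __getitem__(self, cid: str) -> CompoundRecord:
        for r in self.records:
            if r.id == cid:
                return r
        raise KeyError(cid)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def activities(self) -> np.ndarray:
        return np.array([r.activity for r in self.records], dtype=float)

    def subset(self, ids: Iterable[str], role: str | None = None) -> "CompoundSet":
        wanted = list(ids)
        by_id = {r.id: r for r in self.records}
        missing = [i for i in wanted if i not in by_id]
        if missing:
            raise KeyError(f"ids not in set: {missing}")
        recs = [
            replace(by_id[i], role=role if role is not None else by_id[i].role)
            for i in wanted
        ]
        return CompoundSet(records=recs, provenance=self.provenance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "ic50_uM": [r.ic50 for r in self.records],
                "activity": [r.activity for r in self.records],
                "role": [r.role for r in self.records],
            }
        )

    def write(self, path: str | Path, sep: str = ",") -> None:
        df = self.to_frame()[["id", "smiles", "ic50_uM"]]
        if df["smiles"].isna().all():
            df = df.drop(columns="smiles")
        df.to_csv(path, sep=sep, index=False)


def _sniff_sep(path: Path) -> str:
    header = path.read_text(encoding="utf-8").splitlines()[0]
    return "\t" if "\t" in header else ","


def load_compound_table(path: str | Path, sep: str | None = None) -> CompoundSet:
    """Read a delimited compound table (columns ``id``, ``ic50_uM``, optional
    ``smiles``) into a :class:`CompoundSet` with activities auto-computed.

    Errors name the offending row/compound; an empty file is an error rather
    than an empty set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0 or not path.read_text(encoding="utf-8").strip():
        raise ValueError(f"{path}: file is empty")
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"id": str})
    missing = {"id", "ic50_uM"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    errors: list[str] = []
    records: list[CompoundRecord] = []
    for i, row in df.iterrows():
        cid = row["id"]
        if not isinstance(cid, str) or not cid.strip():
            errors.append(f"row {i}: empty id")
            continue
        try:
            ic50 = float(row["ic50_uM"])
        except (TypeError, ValueError):
            errors.append(f"row {i} ({cid}): unparseable ic50_uM {row['ic50_uM']!r}")
            continue
        smiles = row.get("smiles")
        if isinstance(smiles, float) and math.isnan(smiles):
            smiles = None
        try:
            records.append(CompoundRecord(id=cid.strip(), ic50=ic50, smiles=smiles))
        except ValueError as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    return CompoundSet(records=records, provenance=str(path))


def load_table1() -> CompoundSet:
    """Load the packaged 34-compound dihydropteridone activity table.

    IC50 values (µM, PLK1-inhibition cytotoxicity) for the two published
    series 13a–13v and 21A–21L; substituent structures are not machine
    readable and are not included.
    """
    ref = importlib.resources.files("glioqsar") / "data" / "compounds.csv"
    with importlib.resources.as_file(ref) as p:
        cset = load_compound_table(p)
    cset.provenance = "packaged dihydropteridone activity table (34 compounds)"
    return cset


@dataclass(frozen=True)
class SplitSpec:
    """Seeded random partition specification.

    ``held_out_ratio`` is the held-out:train ratio — ``Fraction(1, 3)`` means
    1:3 (a quarter of the data held out), ``Fraction(1, 4)`` means 1:4
    (a fifth held out).  The held-out partition size is the round-half-even of
    ``n * ratio/(1+ratio)``.
    """

    held_out_ratio: Fraction = Fraction(1, 3)
    seed: int = 0
    scheme_label: str = "test"

    @property
    def held_out_fraction(self) -> Fraction:
        return self.held_out_ratio / (1 + self.held_out_ratio)


def split_dataset(
    cset: CompoundSet, spec: SplitSpec
) -> tuple[CompoundSet, CompoundSet]:
    """Partition a compound set into (train, held_out) per a seeded SplitSpec.

    The partition is disjoint and exhaustive, reproducible per seed, and the
    held-out size equals ``round(n * fraction)``.  Roles are stamped on the
    returned records (``train`` and the spec's ``scheme_label``).
    """
    n = len(cset)
    if n < 2:
        raise ValueError("need at least 2 compounds to split")
    frac = spec.held_out_fraction
    if not (0 < frac < 1):
        raise ValueError(f"held-out fraction must be in (0,1), got {frac}")
    n_held = round(n * frac)  # round-half-even: 34 at 1:3 -> 8
    if n_held == 0 or n_held == n:
        raise ValueError(
            f"fraction {frac} yields an empty partition for n={n}"
        )
    rng = np.random.default_rng(spec.seed)
    held_idx = set(rng.choice(n, size=n_held, replace=False).tolist())
    held_ids = [cset.records[i].id for i in range(n) if i in held_idx]
    train_ids = [cset.records[i].id for i in range(n) if i not in held_idx]
    role = spec.scheme_label if spec.scheme_label in ROLES else "test"
    return cset.subset(train_ids, role="train"), cset.subset(held_ids, role=role)


class DescriptorTable:
    """Named numeric descriptor matrix over an ordered compound set.

    Thin wrapper over a pandas DataFrame (index = compound ids, columns =
    descriptor names) enforcing unique names and no missing values.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.columns.duplicated().any():
            dupes = frame.columns[frame.columns.duplicated()].tolist()
            raise ValueError(f"duplicate descriptor names: {dupes}")
        if frame.index.duplicated().any():
            dupes = frame.index[frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate compound ids: {dupes}")
        if frame.isna().any().any():
            bad = frame.columns[frame.isna().any()].tolist()
            raise ValueError(
                f"missing values in descriptor columns {bad}; drop or impute "
                "explicitly before constructing a DescriptorTable"
            )
        self.frame = frame.astype(float)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()

    def select(self, names: Sequence[str]) -> "DescriptorTable":
        missing = [n for n in names if n not in self.frame.columns]
        if missing:
            raise KeyError(f"descriptors not in table: {missing}")
        return DescriptorTable(self.frame[list(names)])

    def drop(self, names: Sequence[str]) -> "DescriptorTable":
        return DescriptorTable(self.frame.drop(columns=list(names)))

    def rows(self, ids: Sequence[str]) -> "DescriptorTable":
        missing = [i for i in ids if i not in self.frame.index]
        if missing:
            raise KeyError(f"compounds not in table: {missing}")
        return DescriptorTable(self.frame.loc[list(ids)])

    def row_dict(self, cid: str) -> dict[str, float]:
        return self.frame.loc[cid].to_dict()

    def write(self, path: str | Path, sep: str = ",") -> None:
        self.frame.to_csv(path, sep=sep, index_label="id")

    @classmethod
    def read(cls, path: str | Path, sep: str | None = None) -> "DescriptorTable":
        path = Path(path)
        if sep is None:
            sep = _sniff_sep(path)
        return cls(pd.read_csv(path, sep=sep, index_col=0))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DescriptorTable) and self.frame.equals(other.frame)


@dataclass(frozen=True)
class RegistryEntry:
    description: str
    coefficient: float
    t_value: float


#: The six descriptors of the published six-parameter linear model, with
#: their printed regression coefficients and t statistics.
DESCRIPTOR_REGISTRY: Mapping[str, RegistryEntry] = {
    "NFA": RegistryEntry("Number of F atoms", 2.9798e-01, 4.0171),
    "MRCH": RegistryEntry("Max e-e repulsion for a C-H bond", 4.4403e-01, 2.5384),
    "MECN": RegistryEntry("Min exchange energy for a C-N bond", 5.6298e00, 3.3342),
    "TEIZP": RegistryEntry(
        "Topographic electronic index (all bonds) [Zefirov's PC]",
        -5.7965e-01,
        -3.1843,
    ),
    "ZXS": RegistryEntry("ZX Shadow / ZX Rectangle", 3.6953e00, 2.7395),
    "MCIHN": RegistryEntry(
        "Min coulombic interaction for a H-N bond", -3.8370e00, -1.5254
    ),
}
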