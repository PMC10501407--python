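"""Candidate-analog generation and activity ranking.

New analogs are enumerated from a template compound by applying entries of
an explicit modification library — descriptor-delta vectors for the 2D
branch and structure edits for the 3D branch (the published 200-analog
design round cannot be regenerated: the concrete substituent choices were
never disclosed, so the mechanism is exposed instead).  Every candidate is
scored by each supplied model and ranked by the designated primary model,
descending, with ties broken by id.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from glioqsar.comsia import AlignedMolecule, PlsQsarModel
from glioqsar.gep import UNDEFINED, ExpressionTree, evaluate_tree
from glioqsar.hm import LinearQsarModel, evaluate_linear

log = logging.getLogger(__name__)


@dataclass
class Modification:
    """One library entry: a named descriptor perturbation and/or a
    structure edit (a pure function molecule -> molecule)."""

    label: str
    descriptor_deltas: dict[str, float] | None = None
    structure_edit: Callable[[AlignedMolecule], AlignedMolecule] | None = None

    def is_identity(self) -> bool:
        return not self.descriptor_deltas and self.structure_edit is None


@dataclass
class CandidateCompound:
    """A designed analog: template provenance, inputs for the models that
    will score it, and the per-model predictions."""

    id: str
    provenance: str = ""
    descriptors: dict[str, float] | None = None
    molecule: AlignedMolecule | None = None
    predictions: dict[str, float] = field(default_factory=dict)


@dataclass
class DesignRun:
    """Ranked outcome of one design round."""

    template_id: str
    candidates: list[CandidateCompound]
    ranking: list[str]  # candidate ids, best first
    primary_model: str
    models_used: list[str]
    seed: int
    errors: dict[str, str] = field(default_factory=dict)

    def top(self, n: int = 8) -> pd.DataFrame:
        frame = self.to_frame()
        return frame.head(min(n, len(frame)))

    def to_frame(self) -> pd.DataFrame:
        by_id = {c.id: c for c in self.candidates}
        rows = []
        for rank, cid in enumerate(self.ranking, start=1):
            c = by_id[cid]
            row = {"rank": rank, "id": cid}
            row.update({f"pred_{m}": v for m, v in c.predictions.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def enumerate_candidates(
    template: CandidateCompound,
    modification_library: Sequence[Modification],
    n: int,
    seed: int = 0,
    with_replacement: bool = False,
) -> list[CandidateCompound]:
    """Apply ``n`` seeded draws from the modification library to the
    template; candidate ids are ``<template>.1 … <template>.n``.

    Without replacement the library must hold at least ``n`` entries.
    """
    if not modification_library:
        raise ValueError("modification library is empty")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not with_replacement and n > len(modification_library):
        raise ValueError(
            f"library holds {len(modification_library)} modifications < n={n}; "
            "pass with_replacement=True to reuse entries"
        )
    rng = np.random.default_rng(seed)
    idx = (
        rng.choice(len(modification_library), size=n, replace=False)
        if not with_replacement
        else rng.integers(0, len(modification_library), size=n)
    )
    out: list[CandidateCompound] = []
    for i, j in enumerate(idx, start=1):
        mod = modification_library[int(j)]
        desc = dict(template.descriptors) if template.descriptors else None
        if mod.descriptor_deltas:
            if desc is None:
                raise ValueError(
                    f"modification {mod.label!r} perturbs descriptors but the "
                    "template carries none"
                )
            for k, dv in mod.descriptor_deltas.items():
                desc[k] = desc.get(k, 0.0) + dv
        mol = template.molecule
        if mod.structure_edit is not None:
            if mol is None:
                raise ValueError(
                    f"modification {mod.label!r} edits structure but the "
                    "template carries no molecule"
                )
            mol = mod.structure_edit(mol)
        out.append(
            CandidateCompound(
                id=f"{template.id}.{i}",
                provenance=f"{template.id} + {mod.label}",
                descriptors=desc,
                molecule=mol,
            )
        )
    return out


def _score(model, cand: CandidateCompound) -> float:
    if isinstance(model, LinearQsarModel):
        if cand.descriptors is None:
            raise ValueError("candidate carries no descriptor vector")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return evaluate_linear(model, cand.descriptors)
    if isinstance(model, ExpressionTree):
        if cand.descriptors is None:
            raise ValueError("candidate carries no descriptor vector")
        v = evaluate_tree(model, cand.descriptors)
        if v is UNDEFINED:
            raise ValueError("expression undefined at candidate descriptors")
        return v
    if isinstance(model, PlsQsarModel):
        if cand.molecule is None:
            raise ValueError("candidate carries no aligned structure")
        return model.predict_molecule(cand.molecule)
    raise TypeError(f"unsupported model type {type(model).__name__}")


def predict_and_rank(
    candidates: Sequence[CandidateCompound],
    models: Mapping[str, object],
    primary_model: str | None = None,
    seed: int = 0,
) -> DesignRun:
    """Score every candidate with every model and rank by the primary
    model's prediction, descending; equal predictions order by id.

    The default primary model prefers the 3D field model, then the GEP
    expression, then the linear model.  Candidates a model cannot score are
    logged and excluded from the ranking (prediction is read-only: model
    and candidate objects are not mutated beyond recording predictions).
    """
    if not models:
        raise ValueError("no models supplied")
    if primary_model is None:
        for name, m in models.items():
            if isinstance(m, PlsQsarModel):
                primary_model = name
                break
        else:
            for name, m in models.items():
                if isinstance(m, ExpressionTree):
                    primary_model = name
                    break
            else:
                primary_model = next(iter(models))
    if primary_model not in models:
        raise KeyError(f"primary model {primary_model!r} not among models")
    errors: dict[str, str] = {}
    for cand in candidates:
        for mname, model in models.items():
            try:
                cand.predictions[mname] = float(_score(model, cand))
            except (ValueError, KeyError, TypeError) as exc:
                errors[f"{cand.id}/{mname}"] = str(exc)
                log.warning("candidate %s: %s scoring failed: %s",
                            cand.id, mname, exc)
    scored = [c for c in candidates if primary_model in c.predictions]
    ranking = [
        c.id
        for c in sorted(scored, key=lambda c: (-c.predictions[primary_model], c.id))
    ]
    template_id = candidates[0].id.rsplit(".", 1)[0] if candidates else ""
    return DesignRun(
        template_id=template_id,
        candidates=list(candidates),
        ranking=ranking,
        primary_model=primary_model,
        models_used=list(models),
        seed=seed,
        errors=errors,
    )


def descriptor_delta_library(
    names: Sequence[str], magnitudes: Sequence[float] | float = 0.5, n: int = 200,
    seed: int = 0,
) -> list[Modification]:
    """Convenience 2D library: seeded sparse descriptor-delta vectors over
    ``names`` (1–3 perturbed descriptors per entry)."""
    rng = np.random.default_rng(seed)
    if isinstance(magnitudes, (int, float)):
        magnitudes = [float(magnitudes)] * len(names)
    mods = []
    for i in range(n):
        k = int(rng.integers(1, min(3, len(names)) + 1))
        picks = rng.choice(len(names), size=k, replace=False)
        deltas = {
            names[j]: float(rng.normal(0.0, magnitudes[j])) for j in picks
        }
        mods.append(Modification(label=f"delta{i + 1}", descriptor_deltas=deltas))
    return mods


def structure_jitter_library(
    template: AlignedMolecule, n: int = 200, seed: int = 0,
    position_sd: float = 0.5, hydro_sd: float = 0.4,
) -> list[Modification]:
    """Convenience 3D library: edits that displace one non-scaffold atom and
    shift its hydrophobicity (seeded, pure per entry)."""
    rng = np.random.default_rng(seed)
    scaffold = set(template.scaffold_map or [])
    editable = [i for i in range(template.n_atoms) if i not in scaffold]
    if not editable:
        raise ValueError("template has no editable (non-scaffold) atoms")
    mods = []
    for k in range(n):
        atom = int(editable[rng.integers(len(editable))])
        dxyz = rng.normal(0.0, position_sd, size=3)
        dh = float(rng.normal(0.0, hydro_sd))

        def edit(mol: AlignedMolecule, atom=atom, dxyz=dxyz, dh=dh) -> AlignedMolecule:
            out = mol.translated(np.zeros(3))  # deep copy
            out.coords[atom] = out.coords[atom] + dxyz
            out.hydrophobicity[atom] += dh
            return out

        mods.append(Modification(label=f"jitter{k + 1}(atom {atom})",
                                 structure_edit=edit))
    return mods
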