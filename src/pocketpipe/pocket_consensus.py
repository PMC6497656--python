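"""Multi-detector pocket ingestion and z-score consensus ranking.

Pocket detectors (alpha-shape servers, cavity-grid servers, solvent-mapping
servers) score pockets in mutually incommensurable units. Following the
Metapocket recipe, raw scores are standardized to z-scores separately within
each method and the top-k pockets per method are carried forward. Detectors
that report no comparable score (e.g. solvent-mapping site lists) may be
loaded with a null score; they are excluded from the ranking.

Input schema (JSON, list of records; CSV variant with the same columns):

    method       detector name, e.g. "castp"
    pocket_id    detector-local pocket identifier
    raw_score    number in the detector's native units, or null/empty
    residues     lining residues as "CHAIN:RESNUM[:ICODE]" tokens
                 (JSON: list of tokens; CSV: ';'-joined string)
    atoms        optional lining atoms as "CHAIN:RESNUM:ATOMNAME" tokens
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field
from typing import IO, Optional, Union

import numpy as np
import pandas as pd

from .structio import ResidueId

#: (chain_id, res_seq, insertion_code, atom_name)
AtomId = tuple[str, int, str, str]


class SchemaError(ValueError):
    """A pocket record is missing a required field or is malformed."""


class DuplicatePocketError(ValueError):
    pass


def parse_residue_token(token: str) -> ResidueId:
    """Parse "A:169" or "A:169:B" into (chain, number, insertion_code)."""
    parts = str(token).strip().split(":")
    if len(parts) not in (2, 3) or not parts[0]:
        raise SchemaError(f"bad residue token {token!r} (expected CHAIN:RESNUM[:ICODE])")
    try:
        num = int(parts[1])
    except ValueError as exc:
        raise SchemaError(f"bad residue number in token {token!r}") from exc
    icode = parts[2] if len(parts) == 3 else ""
    return (parts[0], num, icode)


def parse_atom_token(token: str) -> AtomId:
    parts = str(token).strip().split(":")
    if len(parts) != 3:
        raise SchemaError(f"bad atom token {token!r} (expected CHAIN:RESNUM:ATOMNAME)")
    try:
        num = int(parts[1])
    except ValueError as exc:
        raise SchemaError(f"bad residue number in atom token {token!r}") from exc
    return (parts[0], num, "", parts[2])


@dataclass
class PocketPrediction:
    """One detector's pocket: native-unit score and lining residues/atoms."""

    method: str
    pocket_id: str
    raw_score: Optional[float]
    lining_residues: set[ResidueId]
    lining_atoms: Optional[set[AtomId]] = None

    def __post_init__(self) -> None:
        if not self.lining_residues:
            raise SchemaError(f"pocket {self.method}/{self.pocket_id}: no lining residues")
        if self.raw_score is not None and not math.isfinite(self.raw_score):
            raise SchemaError(f"pocket {self.method}/{self.pocket_id}: non-finite raw_score")

    @property
    def key(self) -> tuple[str, str]:
        return (self.method, self.pocket_id)


@dataclass
class RankedPocket:
    prediction: PocketPrediction
    zscore: float
    rank_in_method: int
    selected: bool


def _record_to_prediction(rec: dict, index: int) -> PocketPrediction:
    for fieldname in ("method", "pocket_id", "residues"):
        if fieldname not in rec or rec[fieldname] in (None, ""):
            raise SchemaError(f"record {index}: missing field {fieldname!r}")
    raw = rec.get("raw_score")
    if raw in (None, ""):
        score: Optional[float] = None
    else:
        try:
            score = float(raw)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"record {index}: raw_score {raw!r} is not numeric") from exc
    residues = rec["residues"]
    if isinstance(residues, str):
        residues = [t for t in residues.split(";") if t.strip()]
    atoms = rec.get("atoms")
    if isinstance(atoms, str):
        atoms = [t for t in atoms.split(";") if t.strip()]
    if isinstance(atoms, float) and math.isnan(atoms):
        atoms = None
    return PocketPrediction(
        method=str(rec["method"]),
        pocket_id=str(rec["pocket_id"]),
        raw_score=score,
        lining_residues={parse_residue_token(t) for t in residues},
        lining_atoms={parse_atom_token(t) for t in atoms} if atoms else None,
    )


def load_pocket_predictions(source: Union[str, os.PathLike, IO[str]]) -> list[PocketPrediction]:
    """Load pocket records from a JSON list or CSV file.

    Raises :class:`SchemaError` naming the record index on malformed records
    and :class:`DuplicatePocketError` on repeated (method, pocket_id) keys.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(os.fspath(source)) as handle:
            text = handle.read()
    stripped = text.lstrip()
    if stripped.startswith("["):
        records = json.loads(text)
    else:
        df = pd.read_csv(pd.io.common.StringIO(text))
        records = df.to_dict(orient="records")
        for rec in records:
            for k, v in list(rec.items()):
                if isinstance(v, float) and math.isnan(v):
                    rec[k] = None

    predictions = []
    seen: set[tuple[str, str]] = set()
    for i, rec in enumerate(records):
        pred = _record_to_prediction(rec, i)
        if pred.key in seen:
            raise DuplicatePocketError(f"duplicate pocket {pred.key}")
        seen.add(pred.key)
        predictions.append(pred)
    return predictions


def zscore_rank(predictions: list[PocketPrediction], k: int = 3) -> list[RankedPocket]:
    """Standardize scores within each method and flag the top-k per method.

    z = (raw − mean) / sd with the sample sd (n−1 denominator). A method with
    a single pocket gets z = 0 and rank 1; zero-variance methods get all
    z = 0 with a warning, ranked by the tie-break. Ties on z are broken by
    larger lining-residue count, then pocket_id. Scoreless pockets
    (raw_score None) are excluded.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    scored = [p for p in predictions if p.raw_score is not None]
    by_method: dict[str, list[PocketPrediction]] = {}
    for p in scored:
        by_method.setdefault(p.method, []).append(p)

    ranked: list[RankedPocket] = []
    for method, pockets in by_method.items():
        raw = np.array([p.raw_score for p in pockets], dtype=float)
        if len(pockets) == 1:
            z = np.zeros(1)
        else:
            sd = raw.std(ddof=1)
            if sd == 0.0:
                warnings.warn(
                    f"method {method!r}: zero variance in raw scores; all z-scores set to 0",
                    stacklevel=2,
                )
                z = np.zeros_like(raw)
            else:
                z = (raw - raw.mean()) / sd
        order = sorted(
            range(len(pockets)),
            key=lambda i: (-z[i], -len(pockets[i].lining_residues), pockets[i].pocket_id),
        )
        for rank0, i in enumerate(order):
            ranked.append(
                RankedPocket(
                    prediction=pockets[i],
                    zscore=float(z[i]),
                    rank_in_method=rank0 + 1,
                    selected=rank0 < k,
                )
            )
    return ranked


def selected_predictions(ranked: list[RankedPocket]) -> list[PocketPrediction]:
    """Union of per-method top-k pockets, in ranking order."""
    return [r.prediction for r in ranked if r.selected]


def ranking_table(ranked: list[RankedPocket]) -> pd.DataFrame:
    rows = [
        {
            "method": r.prediction.method,
            "pocket_id": r.prediction.pocket_id,
            "raw_score": r.prediction.raw_score,
            "zscore": r.zscore,
            "rank_in_method": r.rank_in_method,
            "selected": r.selected,
            "n_lining_residues": len(r.prediction.lining_residues),
        }
        for r in ranked
    ]
    return pd.DataFrame(rows).sort_values(["method", "rank_in_method"]).reset_index(drop=True)
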