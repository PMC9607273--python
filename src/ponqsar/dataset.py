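"""Compound tables for PON1 QSAR modelling.

Human serum paraoxonase-1 (PON1) exists as two position-192 polymorphic
isozymes, Q (Gln192) and R (Arg192), whose hydrolysis rates differ in a
substrate-dependent way.  The packaged dataset holds 30 substrates —
lactones, thiolactones, phenyl acetate and five organophosphates — with
relative hydrolysis rates for each isozyme on a scale where phenyl acetate
is 100.  The modelling response is the base-10 logarithm of that rate, so
the reference compound sits exactly at 2.

Structures are stored as curated SMILES (the curation, including explicit
stereocentres, is offline; this module never converts names to structures
at run time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

Isozyme = Literal["Q", "R"]

#: columns required in a compound table
_REQUIRED = ("id", "smiles")
_MIN_HEAVY_ATOMS = 3


class DatasetError(ValueError):
    """Raised for malformed or invalid compound tables."""


@dataclass(frozen=True)
class CompoundRecord:
    """One substrate with its per-isozyme relative hydrolysis rates."""

    compound_id: str
    name: str
    smiles: str
    rate_q: float
    rate_r: float
    is_test_q: bool = False
    is_test_r: bool = False

    def rate(self, isozyme: Isozyme) -> float:
        return self.rate_q if isozyme == "Q" else self.rate_r

    def is_test(self, isozyme: Isozyme) -> bool:
        return self.is_test_q if isozyme == "Q" else self.is_test_r


@dataclass
class CompoundSet:
    """An ordered collection of :class:`CompoundRecord`."""

    records: list[CompoundRecord] = field(default_factory=list)
    response_name: str = "log_rate_q"

    def __post_init__(self) -> None:
        validate_records(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> CompoundRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    def rates(self, isozyme: Isozyme) -> np.ndarray:
        return np.array([r.rate(isozyme) for r in self.records], dtype=float)

    def test_mask(self, isozyme: Isozyme) -> np.ndarray:
        return np.array([r.is_test(isozyme) for r in self.records], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "name": [r.name for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "rate_q": [r.rate_q for r in self.records],
                "rate_r": [r.rate_r for r in self.records],
                "is_test_q": [int(r.is_test_q) for r in self.records],
                "is_test_r": [int(r.is_test_r) for r in self.records],
            }
        )


def validate_records(records: Sequence[CompoundRecord]) -> None:
    """Check id uniqueness, structure validity and rate positivity."""
    if not records:
        raise DatasetError("empty dataset: no compound rows found")
    seen: set[str] = set()
    for row, rec in enumerate(records, start=1):
        if rec.compound_id in seen:
            raise DatasetError(
                f"duplicate compound id {rec.compound_id!r} at row {row}"
            )
        seen.add(rec.compound_id)
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            raise DatasetError(
                f"unparseable SMILES for compound {rec.compound_id!r} "
                f"({rec.name!r}): {rec.smiles!r}"
            )
        if mol.GetNumHeavyAtoms() < _MIN_HEAVY_ATOMS:
            raise DatasetError(
                f"compound {rec.compound_id!r} has fewer than "
                f"{_MIN_HEAVY_ATOMS} heavy atoms"
            )
        for label, rate in (("rate_q", rec.rate_q), ("rate_r", rec.rate_r)):
            if not math.isfinite(rate) or rate <= 0:
                raise DatasetError(
                    f"non-positive {label}={rate!r} for compound "
                    f"{rec.compound_id!r}: log response undefined"
                )


def load_compound_table(
    path: str | Path, response_name: str = "log_rate_q"
) -> CompoundSet:
    """Load a delimited compound table (comma default, tab accepted).

    Required columns: ``id``, ``smiles``; rate columns ``rate_q``/``rate_r``
    (a single ``rate`` column is broadcast to both); optional flag columns
    ``is_test_q``/``is_test_r``.  Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise DatasetError(f"missing required column(s): {', '.join(missing)}")
    if "rate_q" not in df.columns or "rate_r" not in df.columns:
        if "rate" in df.columns:
            df = df.assign(rate_q=df["rate"], rate_r=df["rate"])
        else:
            raise DatasetError(
                "missing rate columns: need rate_q and rate_r (or rate)"
            )
    if len(df) == 0:
        raise DatasetError("empty dataset: file contains only a header")

    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            CompoundRecord(
                compound_id=str(d["id"]),
                name=str(d.get("name", d["id"])),
                smiles=str(d["smiles"]),
                rate_q=float(d["rate_q"]),
                rate_r=float(d["rate_r"]),
                is_test_q=bool(int(d.get("is_test_q", 0) or 0)),
                is_test_r=bool(int(d.get("is_test_r", 0) or 0)),
            )
        )
    return CompoundSet(records=records, response_name=response_name)


def write_compound_table(cset: CompoundSet, path: str | Path) -> None:
    """Write a CompoundSet in the same delimited format `load` reads."""
    cset.to_frame().to_csv(path, index=False)


def log_response(
    cset: CompoundSet, isozyme: Isozyme, base: float = 10.0
) -> np.ndarray:
    """Log-transformed relative hydrolysis rates for one isozyme.

    Base 10 by default (QSAR convention: phenyl acetate at rate 100 maps
    to exactly 2.0); configurable for other conventions.
    """
    rates = cset.rates(isozyme)
    if np.any(rates <= 0):
        bad = cset.ids[int(np.argmax(rates <= 0))]
        raise DatasetError(f"non-positive rate for compound {bad!r}")
    return np.log(rates) / np.log(base)


def load_pon1() -> CompoundSet:
    """The packaged 30-substrate PON1 dataset.

    Test-set flags follow the printed markings of the source table
    verbatim: 6 compounds flagged for the Q isozyme, 5 for R.  The
    rule-based ordered split (every fifth compound by descending
    response) is available separately and is the normative 80:20 rule.
    """
    with resources.as_file(
        resources.files("ponqsar.data").joinpath("pon1_table1.csv")
    ) as p:
        return load_compound_table(p)
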