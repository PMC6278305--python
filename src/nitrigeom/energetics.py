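"""Conformer-pair energy differences for nitrite binding-mode preference.

Relaxed conformers come in matched pairs: one optimisation started from the
top-hat (bidentate O,O) orientation and one from the N-bound orientation of
the same snapshot/chain/oxidation state.  Absolute energies are never
comparable across snapshots (different atom counts, different solvent
shells), so the only physically meaningful quantity is the within-pair
difference

    Delta-E = E(top-hat) - E(N-bound)        [kcal/mol]

with Delta-E > 0 meaning the N-bound orientation is favoured.  Conformers
whose optimisation collapsed to an artefactual short Cu-O contact with the
Asp97/Asn97 sidechain carry a flag and are discarded before pairing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConformerEnergyRecord",
    "DeltaE",
    "DeltaESummary",
    "FilterResult",
    "PairingResult",
    "SHORT_CU_O_FLAG",
    "filter_conformers",
    "pair_and_delta",
    "summarize_delta",
    "read_energy_table",
    "records_to_frame",
    "summary_table",
]

SHORT_CU_O_FLAG = "short_CuO_contact"
_OXIDATION_STATES = ("CuI", "CuII")
_ORIENTATIONS = ("top-hat", "N-bound")


@dataclass(frozen=True)
class ConformerEnergyRecord:
    """Energy of one relaxed conformer (relative scale within its pair)."""

    system: str  # e.g. D97, D97p, D97N
    snapshot_id: str
    chain: str
    oxidation_state: str  # CuI | CuII
    start_orientation: str  # top-hat | N-bound
    energy: float  # kcal/mol
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.oxidation_state not in _OXIDATION_STATES:
            raise ValueError(f"oxidation_state must be one of {_OXIDATION_STATES}")
        if self.start_orientation not in _ORIENTATIONS:
            raise ValueError(f"start_orientation must be one of {_ORIENTATIONS}")
        if not math.isfinite(self.energy):
            raise ValueError("energy must be finite")
        object.__setattr__(self, "flags", frozenset(self.flags))

    @property
    def pair_key(self) -> tuple[str, str, str, str]:
        return (self.system, self.snapshot_id, self.chain, self.oxidation_state)


@dataclass(frozen=True)
class DeltaE:
    system: str
    snapshot_id: str
    chain: str
    oxidation_state: str
    value: float  # E(top-hat) - E(N-bound), kcal/mol


@dataclass(frozen=True)
class DeltaESummary:
    """Per-(system, oxidation state) aggregation of Delta-E values."""

    system: str
    oxidation_state: str
    n_pairs: int
    mean: float
    std: float
    per_pair: tuple[float, ...]
    interpretation: str

    def __post_init__(self) -> None:
        assert self.n_pairs == len(self.per_pair)


@dataclass
class FilterResult:
    kept: list[ConformerEnergyRecord]
    discarded: list[ConformerEnergyRecord]
    log: list[str]


@dataclass
class PairingResult:
    deltas: list[DeltaE]
    unpaired: list[ConformerEnergyRecord]


def filter_conformers(
    records: Sequence[ConformerEnergyRecord], drop_flagged: bool = True
) -> FilterResult:
    """Discard conformers flagged with an artefactual short Cu-O contact.

    Every removal is logged; with ``drop_flagged=False`` the input passes
    through unchanged (the log still notes flagged records).
    """
    kept, discarded, log = [], [], []
    for rec in records:
        if drop_flagged and SHORT_CU_O_FLAG in rec.flags:
            discarded.append(rec)
            log.append(
                f"discarded {rec.system}/{rec.snapshot_id}/{rec.chain}/"
                f"{rec.oxidation_state}/{rec.start_orientation}: {', '.join(sorted(rec.flags))}"
            )
        else:
            kept.append(rec)
            if rec.flags:
                log.append(
                    f"kept flagged record {rec.system}/{rec.snapshot_id}/{rec.chain}: "
                    f"{', '.join(sorted(rec.flags))}"
                )
    return FilterResult(kept=kept, discarded=discarded, log=log)


def pair_and_delta(records: Sequence[ConformerEnergyRecord]) -> PairingResult:
    """Match top-hat/N-bound records by (system, snapshot, chain, state).

    Delta-E = E(top-hat) - E(N-bound) per complete pair.  Records without a
    partner are reported in ``unpaired`` (with a warning), never silently
    dropped; duplicate records for one key are a hard error.
    """
    by_key: dict[tuple, dict[str, ConformerEnergyRecord]] = {}
    for rec in records:
        slot = by_key.setdefault(rec.pair_key, {})
        if rec.start_orientation in slot:
            raise ValueError(
                f"duplicate {rec.start_orientation} record for "
                f"{'/'.join(rec.pair_key)}"
            )
        slot[rec.start_orientation] = rec

    deltas, unpaired = [], []
    for key, slot in by_key.items():
        if len(slot) == 2:
            deltas.append(
                DeltaE(*key, value=slot["top-hat"].energy - slot["N-bound"].energy)
            )
        else:
            unpaired.extend(slot.values())
    if unpaired:
        warnings.warn(
            f"{len(unpaired)} conformer record(s) had no top-hat/N-bound partner "
            "and were excluded from Delta-E",
            stacklevel=2,
        )
    return PairingResult(deltas=deltas, unpaired=unpaired)


def summarize_delta(
    deltas: Iterable[DeltaE], sample_std: bool = True
) -> list[DeltaESummary]:
    """Mean and std of Delta-E per (system, oxidation state).

    Sample standard deviation (n-1) by default, as appropriate for a small
    set of independent conformer pairs; a single-pair group reports std 0.
    """
    groups: dict[tuple[str, str], list[float]] = {}
    for d in deltas:
        groups.setdefault((d.system, d.oxidation_state), []).append(d.value)
    out = []
    for (system, state), vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        ddof = 1 if sample_std and len(arr) > 1 else 0
        mean = float(arr.mean())
        out.append(
            DeltaESummary(
                system=system,
                oxidation_state=state,
                n_pairs=len(arr),
                mean=mean,
                std=float(arr.std(ddof=ddof)),
                per_pair=tuple(float(v) for v in arr),
                interpretation="N-bound favoured" if mean > 0 else (
                    "top-hat favoured" if mean < 0 else "isoenergetic"
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Tabular I/O

_COLUMNS = ["system", "snapshot", "chain", "oxidation_state", "orientation", "energy", "flags"]


def records_to_frame(records: Sequence[ConformerEnergyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "system": [r.system for r in records],
            "snapshot": [r.snapshot_id for r in records],
            "chain": [r.chain for r in records],
            "oxidation_state": [r.oxidation_state for r in records],
            "orientation": [r.start_orientation for r in records],
            "energy": [r.energy for r in records],
            "flags": [";".join(sorted(r.flags)) for r in records],
        }
    )


def read_energy_table(path: str | Path) -> list[ConformerEnergyRecord]:
    """Read a delimited conformer-energy table (TSV/CSV with header).

    Required columns: system, snapshot, chain, oxidation_state, orientation,
    energy.  Optional: flags (semicolon-separated).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"energy table {path}: missing column(s) {missing}")
    records = []
    for _, row in df.iterrows():
        flags = frozenset()
        if "flags" in df.columns and isinstance(row["flags"], str) and row["flags"]:
            flags = frozenset(row["flags"].split(";"))
        records.append(
            ConformerEnergyRecord(
                system=str(row["system"]),
                snapshot_id=str(row["snapshot"]),
                chain=str(row["chain"]),
                oxidation_state=str(row["oxidation_state"]),
                start_orientation=str(row["orientation"]),
                energy=float(row["energy"]),
                flags=flags,
            )
        )
    return records


def summary_table(summaries: Sequence[DeltaESummary]) -> pd.DataFrame:
    """Render summaries as a table with (mean, std, n) per system and state."""
    return pd.DataFrame(
        {
            "system": [s.system for s in summaries],
            "oxidation_state": [s.oxidation_state for s in summaries],
            "n_pairs": [s.n_pairs for s in summaries],
            "mean_delta_e": [s.mean for s in summaries],
            "std_delta_e": [s.std for s in summaries],
            "interpretation": [s.interpretation for s in summaries],
        }
    )
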