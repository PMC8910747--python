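"""Drug-gene interaction querying and the sequential repurposing filter.

Candidate compounds targeting the selected regulator genes are passed
through four exclusion stages, in order: (1) duplicated (compound, gene)
pairs, (2) compounds flagged inefficacious in clinical trials, (3) compounds
with memory or excitotoxicity side-effect flags, (4) compounds with an
unknown (empty) modality of action.  Each record is disposed exactly once,
at its first failing stage, and the full disposition is returned as an
auditable log.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

FILTER_STAGES = ("duplicated", "inefficacious", "side_effects", "unknown_moa")

_CSV_COLUMNS = [
    "compound_id",
    "compound_name",
    "gene",
    "moa",
    "phase",
    "efficacious",
    "side_effect_memory",
    "side_effect_excitotoxicity",
]


@dataclass(frozen=True)
class InteractionRecord:
    """One drug-gene interaction row from a local interaction table."""

    compound_id: str
    compound_name: str
    gene: str
    moa: str = ""
    phase: str = ""
    efficacious: bool = True
    side_effect_memory: bool = False
    side_effect_excitotoxicity: bool = False
    provenance: str = "local"

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound id must be nonempty")


@dataclass
class FilterLog:
    """Auditable record of the sequential compound filter."""

    initial: int
    removed: dict[str, int]
    final: int
    dispositions: list[tuple[InteractionRecord, str]] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        if self.initial - sum(self.removed.values()) != self.final:
            raise ValueError("filter log arithmetic does not balance")

    def to_dict(self) -> dict:
        return {"initial": self.initial, "removed": dict(self.removed), "final": self.final}


def query_interactions(genes, table: list[InteractionRecord]) -> list[InteractionRecord]:
    """All records whose target gene is in ``genes`` (case-normalized),
    original table order preserved."""
    wanted = {str(g).upper() for g in genes}
    return [rec for rec in table if rec.gene.upper() in wanted]


def filter_compounds(
    records: list[InteractionRecord],
) -> tuple[list[InteractionRecord], FilterLog]:
    """Apply the four exclusion stages in order; see module docstring."""
    removed = {stage: 0 for stage in FILTER_STAGES}
    dispositions: list[tuple[InteractionRecord, str]] = []
    kept: list[InteractionRecord] = []
    seen: set[tuple[str, str]] = set()
    for rec in records:
        key = (rec.compound_id, rec.gene.upper())
        if key in seen:
            stage = "duplicated"
        elif not rec.efficacious:
            stage = "inefficacious"
        elif rec.side_effect_memory or rec.side_effect_excitotoxicity:
            stage = "side_effects"
        elif not rec.moa.strip():
            stage = "unknown_moa"
        else:
            stage = "kept"
            kept.append(rec)
        # first occurrence claims the key even if later excluded
        seen.add(key)
        if stage != "kept":
            removed[stage] += 1
        dispositions.append((rec, stage))
    log = FilterLog(len(records), removed, len(kept), dispositions)
    return kept, log


def drug_report(final_records: list[InteractionRecord]) -> pd.DataFrame:
    """Gene -> drug table for the retained compounds, sorted by (gene, drug)."""
    rows = [
        {
            "gene": rec.gene,
            "drug": rec.compound_name,
            "compound_id": rec.compound_id,
            "phase": rec.phase,
            "moa": rec.moa,
        }
        for rec in final_records
    ]
    df = pd.DataFrame(rows, columns=["gene", "drug", "compound_id", "phase", "moa"])
    return df.sort_values(["gene", "drug"], kind="stable").reset_index(drop=True)


def write_interaction_csv(table: list[InteractionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "compound_name": r.compound_name,
                "gene": r.gene,
                "moa": r.moa,
                "phase": r.phase,
                "efficacious": r.efficacious,
                "side_effect_memory": r.side_effect_memory,
                "side_effect_excitotoxicity": r.side_effect_excitotoxicity,
            }
            for r in table
        ],
        columns=_CSV_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_interaction_csv(path: str | Path) -> list[InteractionRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            InteractionRecord(
                compound_id=str(row.compound_id),
                compound_name=str(row.compound_name),
                gene=str(row.gene),
                moa=str(row.moa),
                phase=str(row.phase),
                efficacious=_as_bool(row.efficacious),
                side_effect_memory=_as_bool(row.side_effect_memory),
                side_effect_excitotoxicity=_as_bool(row.side_effect_excitotoxicity),
            )
        )
    return records


def _as_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in {"true", "1", "yes"}
    return bool(x)
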