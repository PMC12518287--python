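"""Domain types and readers/writers for the tabular and sequence formats the
pipeline touches.

The central object is :class:`SpotTable`, a spots x samples matrix of gel
fluorescence intensities together with a :class:`SampleSheet` describing the
experimental design (organ, condition, biological replicate, gel).  Gels from
different organs are analyzed as independent tables throughout.

File dialect: tab-separated, UTF-8, "." decimal separator; missing
intensities are encoded as empty cells and carried as NaN — never as silent
zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ORGANS = ("shoot", "root")
CONDITIONS = ("control", "anoxia", "reaeration")

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class SampleSheet:
    """Experimental design: one row per sample (gel channel).

    Conditions are restricted to the three-level factor
    control / anoxia / reaeration.
    """

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "organ", "condition", "replicate", "gel_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        frame = self.frame.reset_index(drop=True).copy()
        frame["replicate"] = frame["replicate"].astype(int)
        if frame["sample_id"].duplicated().any():
            dups = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_id in sheet: {dups}")
        bad_cond = set(frame["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(
                f"unknown conditions {sorted(bad_cond)}; allowed: {CONDITIONS}"
            )
        bad_organ = set(frame["organ"]) - set(ORGANS)
        if bad_organ:
            raise ValueError(f"unknown organs {sorted(bad_organ)}; allowed: {ORGANS}")
        if (frame["replicate"] < 1).any():
            raise ValueError("replicate numbers must be positive integers")
        self.frame = frame

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def conditions(self) -> np.ndarray:
        return self.frame["condition"].to_numpy()

    @property
    def replicates(self) -> np.ndarray:
        return self.frame["replicate"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, sample_ids: list[str]) -> "SampleSheet":
        sub = self.frame[self.frame["sample_id"].isin(sample_ids)]
        return SampleSheet(sub)


@dataclass
class SpotTable:
    """Spots x samples intensity matrix plus its design sheet.

    ``matrix`` is float with NaN marking missing spots; pre-log values must be
    non-negative.  ``log_transformed`` / ``normalized`` record the processing
    state so downstream stages can assert their preconditions.
    """

    spot_ids: list[str]
    matrix: np.ndarray
    sheet: SampleSheet
    log_transformed: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-dimensional")
        if self.matrix.shape[0] != len(self.spot_ids):
            raise ValueError("row count does not match number of spot ids")
        if self.matrix.shape[1] != len(self.sheet):
            raise ValueError("column count does not match sample sheet")
        if len(set(self.spot_ids)) != len(self.spot_ids):
            seen: set[str] = set()
            dups = sorted({s for s in self.spot_ids if s in seen or seen.add(s)})
            raise ValueError(f"duplicate spot ids: {dups}")
        if not self.log_transformed and np.nanmin(self.matrix, initial=0) < 0:
            raise ValueError("negative intensities in a pre-log table")

    @property
    def n_spots(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=pd.Index(self.spot_ids, name="spot_id"),
            columns=self.sheet.sample_ids,
        )

    def subset_organ(self, organ: str) -> "SpotTable":
        """Restrict to one organ's samples (organs are analyzed separately)."""
        mask = self.sheet.frame["organ"] == organ
        sub_sheet = SampleSheet(self.sheet.frame[mask])
        return replace(self, sheet=sub_sheet, matrix=self.matrix[:, mask.to_numpy()])


@dataclass
class ProteinRecord:
    """An identified protein: accession, sequence, source organ and the gel
    spots it was observed in."""

    accession: str
    sequence: str
    organ: str = "shoot"
    spot_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.accession}: non-standard residues {sorted(bad)}"
            )


@dataclass
class CategoryCount:
    category: str
    count: int
    fraction: float


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> SampleSheet:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gel_id": str})
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


def read_spot_table(path, sheet_path) -> SpotTable:
    """Read a PDQuest-style export: first column spot id, remaining columns
    named by sample_id.  Columns are reordered to match the sheet; columns
    not present in the sheet are reported via a warning."""
    sheet = sheet_path if isinstance(sheet_path, SampleSheet) else read_sample_sheet(sheet_path)
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    frame.index = frame.index.astype(str)
    if frame.index.duplicated().any():
        dups = sorted(set(frame.index[frame.index.duplicated()]))
        raise ValueError(f"duplicate spot ids in {path}: {dups}")
    missing = [s for s in sheet.sample_ids if s not in frame.columns]
    if missing:
        raise ValueError(f"samples in sheet but absent from table: {missing}")
    extra = [c for c in frame.columns if c not in sheet.sample_ids]
    if extra:
        warnings.warn(f"ignoring columns absent from sheet: {extra}")
    frame = frame[sheet.sample_ids]
    return SpotTable(
        spot_ids=frame.index.tolist(),
        matrix=frame.to_numpy(dtype=float),
        sheet=sheet,
    )


def write_spot_table(table: SpotTable, path) -> None:
    # %.17g round-trips IEEE doubles exactly
    table.to_frame().to_csv(path, sep="\t", na_rep="", float_format="%.17g")


def read_protein_fasta(path, organ: str = "shoot") -> list[ProteinRecord]:
    """Read protein sequences; spot ids may be listed in the description as
    ``spots=a,b,c``."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        spot_ids: list[str] = []
        for token in rec.description.split():
            if token.startswith("spots="):
                spot_ids = token[len("spots="):].split(",")
        records.append(
            ProteinRecord(rec.id, str(rec.seq), organ=organ, spot_ids=spot_ids)
        )
    return records


def write_protein_fasta(records: list[ProteinRecord], path) -> None:
    seq_records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.accession,
            description=f"spots={','.join(r.spot_ids)}" if r.spot_ids else "",
        )
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def dedup_sequences(records: list[ProteinRecord]) -> list[ProteinRecord]:
    """Merge records with byte-identical sequences (100% identity clustering).

    The first record of each identity class is retained, carrying the union
    of spot ids of its duplicates; order of first occurrence is preserved.
    """
    by_seq: dict[str, ProteinRecord] = {}
    out: list[ProteinRecord] = []
    for rec in records:
        kept = by_seq.get(rec.sequence)
        if kept is None:
            kept = replace(rec, spot_ids=list(rec.spot_ids))
            by_seq[rec.sequence] = kept
            out.append(kept)
        else:
            kept.spot_ids = sorted(set(kept.spot_ids) | set(rec.spot_ids))
    return out


def summarize_categories(labels, universe=None) -> list[CategoryCount]:
    """Count functional-category assignments (e.g. COG letters) and report
    per-category fractions over the non-missing labels."""
    clean = [l for l in labels if l is not None and not (isinstance(l, float) and np.isnan(l))]
    if not clean:
        warnings.warn("no category labels to summarize")
        return []
    counts = pd.Series(clean).value_counts()
    if universe is not None:
        counts = counts.reindex(sorted(universe), fill_value=0)
    total = counts.sum()
    return [
        CategoryCount(category=str(cat), count=int(n), fraction=float(n) / total)
        for cat, n in counts.items()
    ]


def categories_to_frame(summary: list[CategoryCount]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.category, c.count, c.fraction) for c in summary],
        columns=["category", "count", "fraction"],
    )
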