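"""Synthetic-data generators emulating the statistical structure of the
2D-DIGE study design.

The study layout is a three-level condition factor (control, anoxia,
re-aeration) with three biological replicates per condition per organ and
roughly 40-90 spots per organ.  Spot intensities follow a log-normal model:
Normal replicate noise is added on the log2 scale to a per-group condition
pattern, and the result is exponentiated back to fluorescence units.  The
four abundance-trajectory groups are encoded as sign patterns of the
condition effect:

    group 1  decrease through anoxia and re-aeration      (+1, -1/2, -1)
    group 2  peak during anoxia                           (-1/2, +1, -1/2)
    group 3  rise in anoxia, peak in re-aeration          (-1, +1/2, +1)
    group 4  dip in anoxia, accumulate in re-aeration     (+1/2, -1, +1)

(multipliers of ``effect_log2`` for the C/A/R condition means).

Promoter generators produce i.i.d. background sequence of a chosen AT
fraction with family-labelled motifs planted at recorded, non-overlapping
positions, so the motif scanner can be validated against exact ground truth.

All generators are pure functions of (parameters, seed); a seed is
mandatory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io import CONDITIONS, ProteinRecord, SampleSheet, SpotTable
from .protchem import peptide_masses, tryptic_digest

GROUP_PATTERNS: dict[int, tuple[float, float, float]] = {
    1: (1.0, -0.5, -1.0),
    2: (-0.5, 1.0, -0.5),
    3: (-1.0, 0.5, 1.0),
    4: (0.5, -1.0, 1.0),
}

IUPAC_CODES = set("ACGTRYSWKMBDHVN")


@dataclass
class TrajectorySpec:
    """Log2-scale parameters for one planted trajectory group."""

    group: int
    base_log2: float = 10.0
    effect_log2: float = 2.0
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.group not in GROUP_PATTERNS:
            raise ValueError(f"group must be 1-4, got {self.group}")
        if self.effect_log2 <= 0:
            raise ValueError("effect_log2 must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PlantedMotifSpec:
    """A motif family planted into synthetic promoters."""

    family: str
    consensus: str
    copies_per_gene: int = 1
    condition_group: str = "control"

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper()
        bad = set(self.consensus) - IUPAC_CODES
        if bad:
            raise ValueError(f"non-IUPAC letters in consensus: {sorted(bad)}")
        if self.copies_per_gene < 0:
            raise ValueError("copies_per_gene must be non-negative")


def default_design(organ: str = "shoot", n_replicates: int = 3) -> SampleSheet:
    """The study design: 3 conditions x n biological replicates, one gel per
    replicate with the three condition channels co-resolved."""
    rows = []
    for cond in CONDITIONS:
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"{organ}_{cond}_{rep}",
                    "organ": organ,
                    "condition": cond,
                    "replicate": rep,
                    "gel_id": f"gel_{organ}_{rep}",
                }
            )
    return SampleSheet(pd.DataFrame(rows))


def generate_spot_table(
    n_spots_per_group: int,
    design: SampleSheet,
    specs: dict[int, TrajectorySpec] | None = None,
    seed: int | None = None,
) -> tuple[SpotTable, pd.Series]:
    """Simulate a spot table with planted four-group trajectory structure.

    Returns the table (intensity scale, fluorescence-like units) and the
    ground-truth group label per spot id.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    if n_spots_per_group < 1:
        raise ValueError("n_spots_per_group must be >= 1")
    if set(design.conditions) != set(CONDITIONS):
        raise ValueError("design must cover all three conditions")
    if specs is None:
        specs = {g: TrajectorySpec(group=g) for g in GROUP_PATTERNS}

    rng = np.random.default_rng(seed)
    cond_idx = np.array([CONDITIONS.index(c) for c in design.conditions])
    spot_ids: list[str] = []
    labels: list[int] = []
    rows: list[np.ndarray] = []
    for group in sorted(specs):
        spec = specs[group]
        pattern = np.array(GROUP_PATTERNS[group])
        for i in range(n_spots_per_group):
            mu = spec.base_log2 + spec.effect_log2 * pattern[cond_idx]
            log2_int = mu + rng.normal(0.0, spec.noise_sd, size=len(design))
            rows.append(2.0 ** log2_int)
            spot_ids.append(f"SSP{group}{i + 1:03d}")
            labels.append(group)
    table = SpotTable(spot_ids=spot_ids, matrix=np.vstack(rows), sheet=design)
    truth = pd.Series(labels, index=spot_ids, name="group")
    return table, truth


def _iupac_choices(letter: str) -> str:
    return {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    }[letter]


def _instantiate(consensus: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_iupac_choices(c))) for c in consensus)


def generate_promoters(
    n_genes: int,
    length: int = 500,
    at_fraction: float = 0.6,
    planted: list[PlantedMotifSpec] | None = None,
    seed: int | None = None,
    max_tries: int = 1000,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Simulate upstream regions with planted, position-recorded motifs.

    Background bases are i.i.d. with P(A)+P(T) = ``at_fraction``.  Motifs are
    inserted at non-overlapping positions (rejection sampling) on a random
    strand; a minus-strand copy is inserted as the reverse complement.  The
    ground-truth table lists gene, family, upstream start coordinate
    (1-based negative offsets, -1 adjacent to the gene start) and strand.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    if not 0 < at_fraction < 1:
        raise ValueError("at_fraction must be in (0, 1)")
    planted = planted or []
    total_planted = sum(len(s.consensus) * s.copies_per_gene for s in planted)
    if total_planted > length:
        raise ValueError(
            f"planted motifs require {total_planted} bases but promoters are "
            f"{length} nt long"
        )

    rng = np.random.default_rng(seed)
    probs = np.array(
        [at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2, at_fraction / 2]
    )
    bases = np.array(list("ACGT"))
    records: list[SeqRecord] = []
    truth_rows = []
    for g in range(n_genes):
        gene_id = f"gene{g + 1:04d}"
        seq = rng.choice(bases, size=length, p=probs)
        occupied: list[tuple[int, int]] = []
        for spec in planted:
            for _ in range(spec.copies_per_gene):
                site = _instantiate(spec.consensus, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                inserted = site if strand == "+" else str(Seq(site).reverse_complement())
                w = len(inserted)
                for _try in range(max_tries):
                    start = int(rng.integers(0, length - w + 1))
                    if all(start + w <= a or start >= b for a, b in occupied):
                        break
                else:
                    raise RuntimeError("could not place motif without overlap")
                occupied.append((start, start + w))
                seq[start:start + w] = list(inserted)
                truth_rows.append(
                    {
                        "gene_id": gene_id,
                        "family": spec.family,
                        "start": start - length,  # upstream frame
                        "strand": strand,
                        "site": site,
                        "condition_group": spec.condition_group,
                    }
                )
        records.append(SeqRecord(Seq("".join(seq)), id=gene_id, description=""))
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "family", "start", "strand", "site", "condition_group"],
    )
    return records, truth


def generate_peaklist(
    record: ProteinRecord | None,
    contaminant: ProteinRecord | None = None,
    noise_peaks: int = 0,
    seed: int | None = None,
    missed_cleavages: int = 2,
    mass_range: tuple[float, float] = (700.0, 3500.0),
) -> list[float]:
    """Simulate an MS1 peptide-fingerprint peak list: the tryptic peptide
    monoisotopic masses of the target and contaminant proteins plus uniform
    noise peaks within the instrument scan window."""
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    rng = np.random.default_rng(seed)
    peaks: list[float] = []
    for prot in (record, contaminant):
        if prot is not None:
            peptides = tryptic_digest(prot.sequence, missed_cleavages=missed_cleavages)
            peaks.extend(peptide_masses(peptides))
    lo, hi = mass_range
    peaks.extend(rng.uniform(lo, hi, size=noise_peaks).tolist())
    return sorted(peaks)


def generate_proteins(
    n: int,
    seed: int | None = None,
    length_range: tuple[int, int] = (120, 450),
    organ: str = "shoot",
) -> list[ProteinRecord]:
    """Random protein sequences with roughly globular-average composition,
    for exercising the physicochemistry stages without real identifications."""
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    rng = np.random.default_rng(seed)
    # approximate vertebrate/plant average residue frequencies
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    freqs = np.array(
        [8.3, 1.4, 5.4, 6.8, 3.9, 7.1, 2.3, 6.0, 5.8, 9.7,
         2.4, 4.1, 4.7, 4.0, 5.5, 6.6, 5.4, 6.9, 1.1, 2.9]
    )
    freqs = freqs / freqs.sum()
    records = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(aas, size=length, p=freqs))
        records.append(
            ProteinRecord(f"SYN{organ.upper()}{i + 1:03d}", seq, organ=organ)
        )
    return records
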