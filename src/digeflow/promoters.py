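"""Upstream-region extraction, AT-content profiling, motif scanning and
per-family binding-site summaries.

Upstream coordinates are 1-based negative offsets relative to the annotated
gene start: position -1 is adjacent to the start, -500 is the distal end of
a full-length promoter.  Motif hits report the leftmost position of the
match in this frame regardless of strand.

The motif library maps transcription-factor families to either IUPAC
consensus strings (matched exactly against degeneracy classes) or position
weight matrices (hits where the log-odds score against a uniform background
reaches a threshold, by default 80% of the maximum achievable score).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class PromoterRecord:
    """An upstream region; ``truncated`` marks promoters shorter than the
    requested length (contig edge)."""

    gene_id: str
    sequence: str
    strand: str = "+"
    truncated: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.gene_id}: unexpected letters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MotifEntry:
    family: str
    motif_id: str
    consensus: str | None = None
    pwm: np.ndarray | None = None  # 4 x width, rows A,C,G,T
    threshold_fraction: float = 0.8

    def __post_init__(self) -> None:
        if (self.consensus is None) == (self.pwm is None):
            raise ValueError("provide exactly one of consensus or pwm")
        if self.consensus is not None:
            self.consensus = self.consensus.upper()
            bad = set(self.consensus) - set(IUPAC_EXPAND)
            if bad:
                raise ValueError(f"malformed IUPAC letters {sorted(bad)}")
        else:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.shape[0] != 4:
                raise ValueError("PWM must have 4 rows (A, C, G, T)")


@dataclass
class MotifHitSet:
    """Per-gene, per-family binding-site hits in the upstream frame."""

    hits: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_id", "family", "motif_id", "start", "strand", "score"]))

    def __len__(self) -> int:
        return len(self.hits)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def extract_upstream(gff_path, genome_path, length: int = 500) -> list[PromoterRecord]:
    """Strand-aware upstream regions from GFF3 gene records and a genome
    FASTA (1-based inclusive coordinates).

    A + strand gene starting at s yields genomic [s-length, s-1]; a - strand
    gene ending at e yields the reverse complement of [e+1, e+length].
    Regions truncated at contig edges are flagged.
    """
    import gffutils

    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_path), "fasta")}
    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out: list[PromoterRecord] = []
    for gene in db.features_of_type("gene"):
        if gene.seqid not in genome:
            raise ValueError(f"contig {gene.seqid!r} for gene {gene.id!r} "
                             "absent from genome")
        contig = genome[gene.seqid]
        if gene.strand == "-":
            lo = gene.end + 1
            hi = min(gene.end + length, len(contig))
            seq = str(Seq(contig[lo - 1:hi]).reverse_complement())
            truncated = hi - lo + 1 < length
        else:
            lo = max(gene.start - length, 1)
            hi = gene.start - 1
            seq = contig[lo - 1:hi]
            truncated = hi - lo + 1 < length
        out.append(PromoterRecord(gene.id, seq, strand=gene.strand or "+",
                                  truncated=truncated))
    return out


def read_promoter_fasta(path) -> list[PromoterRecord]:
    return [PromoterRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def split_promoter(promoter: PromoterRecord) -> tuple[PromoterRecord, PromoterRecord]:
    """Cut a 500 nt promoter into its distal (-500..-251) and proximal
    (-250..-1) 250 nt halves."""
    if len(promoter) != 500:
        raise ValueError(f"{promoter.gene_id}: expected 500 nt, got {len(promoter)}")
    distal = PromoterRecord(promoter.gene_id, promoter.sequence[:250], promoter.strand)
    proximal = PromoterRecord(promoter.gene_id, promoter.sequence[250:], promoter.strand)
    return distal, proximal


# ---------------------------------------------------------------------------
# AT content
# ---------------------------------------------------------------------------

def at_content(sequence: str) -> float:
    """(A + T) / (length - N); N bases are excluded from the denominator."""
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    denom = len(seq) - seq.count("N")
    if denom == 0:
        raise ValueError("sequence is all N")
    return (seq.count("A") + seq.count("T")) / denom


def positional_at_profile(promoters: list[PromoterRecord], window: int = 10,
                          length: int = 500) -> np.ndarray:
    """Per-position fraction of A/T across promoters over -length..-1,
    optionally smoothed by a centered moving average of the given width.
    Sequences are right-aligned at -1; positions with no coverage are NaN."""
    if not promoters:
        raise ValueError("need at least one promoter")
    at = np.zeros(length)
    cov = np.zeros(length)
    for p in promoters:
        seq = p.sequence[-length:]
        offset = length - len(seq)
        for i, base in enumerate(seq):
            if base == "N":
                continue
            cov[offset + i] += 1
            if base in "AT":
                at[offset + i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = at / cov
    if window > 1:
        kernel = np.ones(window) / window
        valid = np.isfinite(profile)
        smoothed = np.convolve(np.where(valid, profile, 0.0), kernel, mode="same")
        norm = np.convolve(valid.astype(float), kernel, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            profile = smoothed / norm
    return profile


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def iupac_regex(consensus: str) -> str:
    parts = []
    for letter in consensus.upper():
        if letter not in IUPAC_EXPAND:
            raise ValueError(f"malformed IUPAC letter {letter!r}")
        opts = IUPAC_EXPAND[letter]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return "".join(parts)


def _scan_consensus(seq: str, consensus: str):
    pattern = re.compile(f"(?=({iupac_regex(consensus)}))")
    return [m.start() for m in pattern.finditer(seq)]


def _scan_pwm(seq: str, pwm: np.ndarray, threshold: float):
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = pwm.shape[1]
    with np.errstate(divide="ignore"):
        logodds = np.log2(np.maximum(pwm, 1e-9) / 0.25)
    hits = []
    for i in range(len(seq) - w + 1):
        window = seq[i:i + w]
        if "N" in window:
            continue
        score = sum(logodds[base_idx[b], j] for j, b in enumerate(window))
        if score >= threshold:
            hits.append((i, float(score)))
    return hits


def scan_motifs(promoters: list[PromoterRecord], library: list[MotifEntry]) -> MotifHitSet:
    """Scan both strands of each promoter with every library motif.

    All (possibly overlapping) hits are reported.  Minus-strand hits are
    mirrored back into the promoter (+ strand) frame, so ``start`` is always
    the leftmost matched base as a negative upstream offset.
    """
    rows = []
    for prom in promoters:
        seq = prom.sequence
        L = len(seq)
        rc = str(Seq(seq).reverse_complement())
        for entry in library:
            if entry.consensus is not None:
                w = len(entry.consensus)
                if w > L:
                    continue
                fwd = [(i, 1.0) for i in _scan_consensus(seq, entry.consensus)]
                rev = [(i, 1.0) for i in _scan_consensus(rc, entry.consensus)]
            else:
                w = entry.pwm.shape[1]
                if w > L:
                    continue
                max_score = float(np.sum(np.max(
                    np.log2(np.maximum(entry.pwm, 1e-9) / 0.25), axis=0)))
                threshold = entry.threshold_fraction * max_score
                fwd = _scan_pwm(seq, entry.pwm, threshold)
                rev = _scan_pwm(rc, entry.pwm, threshold)
            for i, score in fwd:
                rows.append((prom.gene_id, entry.family, entry.motif_id,
                             i - L, "+", score))
            for i, score in rev:
                # leftmost base of the minus-strand match on the + frame
                rows.append((prom.gene_id, entry.family, entry.motif_id,
                             (L - i - w) - L, "-", score))
    hits = pd.DataFrame(rows, columns=["gene_id", "family", "motif_id",
                                       "start", "strand", "score"])
    hits = hits.sort_values(["gene_id", "start", "family", "strand"],
                            kind="mergesort").reset_index(drop=True)
    return MotifHitSet(hits)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def family_summary(hits: MotifHitSet, universe: list[str],
                   grouping: dict[str, str] | None = None,
                   families: list[str] | None = None) -> pd.DataFrame:
    """Per-family summaries over a stated gene universe: the percentage of
    genes with at least one site and the mean number of sites per gene
    (zeros included).  With a grouping (gene -> condition), summaries are
    additionally computed per group."""
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty gene universe")
    h = hits.hits
    stray = set(h["gene_id"]) - set(universe)
    if stray:
        raise ValueError(f"hits reference genes outside the universe: {sorted(stray)}")
    if families is None:
        families = sorted(h["family"].unique())
    groups: dict[str, list[str]] = {"all": universe}
    if grouping is not None:
        for gene in universe:
            groups.setdefault(grouping.get(gene, "ungrouped"), []).append(gene)
    rows = []
    counts = h.groupby(["family", "gene_id"]).size()
    for family in families:
        fam_counts = counts.loc[family] if family in counts.index.get_level_values(0) else pd.Series(dtype=int)
        for group, genes in groups.items():
            per_gene = np.array([fam_counts.get(g, 0) for g in genes])
            rows.append(
                {
                    "family": family,
                    "group": group,
                    "n_genes": len(genes),
                    "pct_genes_with_site": 100.0 * float((per_gene > 0).mean()),
                    "mean_sites_per_gene": float(per_gene.mean()),
                }
            )
    return pd.DataFrame(rows)


def positional_hit_profile(hits: MotifHitSet, bin_width: int = 50,
                           length: int = 500) -> pd.DataFrame:
    """Histogram of hit start coordinates over [-length, -1]; bins cover
    [-500,-451] ... [-50,-1] for the defaults."""
    edges = np.arange(-length, 1, bin_width)  # [-500, -450, ..., 0]
    labels = [f"[{lo},{lo + bin_width - 1}]" for lo in edges[:-1]]
    counts = np.zeros(len(labels), dtype=int)
    for start in hits.hits["start"]:
        if start < -length or start > -1:
            warnings.warn(f"hit start {start} outside [-{length}, -1]; skipped")
            continue
        counts[int((start + length) // bin_width)] += 1
    return pd.DataFrame({"bin": labels, "bin_start": edges[:-1], "count": counts})


# ---------------------------------------------------------------------------
# library I/O
# ---------------------------------------------------------------------------

def read_motif_library(path) -> list[MotifEntry]:
    """TSV motif library: columns family, motif_id, consensus.  Rows whose
    consensus field looks like ``A:...;C:...;G:...;T:...`` are parsed as
    PWMs (comma-separated column probabilities per base)."""
    frame = pd.read_csv(path, sep="\t")
    entries = []
    for _, row in frame.iterrows():
        spec = str(row["consensus"]).strip()
        if spec.startswith("A:"):
            rows = {}
            for part in spec.split(";"):
                base, vals = part.split(":")
                rows[base.strip()] = [float(v) for v in vals.split(",")]
            pwm = np.array([rows[b] for b in "ACGT"])
            entries.append(MotifEntry(row["family"], row["motif_id"], pwm=pwm))
        else:
            entries.append(MotifEntry(row["family"], row["motif_id"], consensus=spec))
    return entries


def default_motif_library() -> list[MotifEntry]:
    """A small curated set of published plant consensus elements (W-box for
    WRKY, GCC-box for ERF, and canonical sites for Myb, TCP, SBP and TBP);
    user libraries can extend or replace it via a TSV file."""
    return [
        MotifEntry("WRKY", "Wbox", consensus="TTGACY"),
        MotifEntry("ERF", "GCCbox", consensus="AGCCGCC"),
        MotifEntry("Myb/SANT", "MybCore", consensus="YAACKG"),
        MotifEntry("TCP", "TCPsite", consensus="GGNCCC"),
        MotifEntry("SBP", "SBPcore", consensus="NNGTACNN"),
        MotifEntry("TBP", "TATAbox", consensus="TATAWAW"),
    ]
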