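"""Sequence-derived protein physicochemistry and in-silico digestion.

Covers molecular weight (average and monoisotopic), isoelectric point by
Henderson-Hasselbalch bisection, residue composition with a between-organ
Welch comparison, positional residue density, ladder-calibrated molecular
weight from gel migration (Rf), tryptic digestion with missed cleavages, and
removal of protease-autolysis peaks from MS1 fingerprints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from statsmodels.stats.multitest import multipletests

# residue masses, Da (monoisotopic, average)
MONOISOTOPIC = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
AVERAGE = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MONO = 18.010565
WATER_AVG = 18.01528
PROTON = 1.00728
CARBAMIDOMETHYL = 57.02146  # fixed Cys modification
MET_OXIDATION = 15.99491    # variable Met modification

# side-chain / termini pKa sets
PKA_SETS: dict[str, dict[str, float]] = {
    # EMBOSS (iep) values
    "emboss": {
        "Nterm": 8.6, "Cterm": 3.6,
        "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
    },
    # Bjellqvist values as used by the ExPASy pI computation (side chains;
    # termini simplified to the generic values)
    "bjellqvist": {
        "Nterm": 7.5, "Cterm": 3.55,
        "C": 9.0, "D": 4.05, "E": 4.45, "H": 5.98, "K": 10.0, "R": 12.0,
        "Y": 10.0,
    },
}

NEGATIVE = ("Cterm", "D", "E", "C", "Y")
POSITIVE = ("Nterm", "K", "R", "H")


def _validate(sequence: str) -> str:
    sequence = sequence.upper()
    if not sequence:
        raise ValueError("empty sequence")
    for i, aa in enumerate(sequence):
        if aa not in MONOISOTOPIC:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}")
    return sequence


def compute_mw(
    sequence: str,
    kind: str = "average",
    cys_carbamidomethyl: bool = False,
) -> float:
    """Molecular weight in Da: sum of residue masses plus one water.

    The fixed carbamidomethyl-Cys modification is applied only when requested
    (peptide-mass use); intact-protein reporting uses unmodified residues.
    """
    sequence = _validate(sequence)
    if kind == "average":
        table, water = AVERAGE, WATER_AVG
    elif kind == "monoisotopic":
        table, water = MONOISOTOPIC, WATER_MONO
    else:
        raise ValueError("kind must be 'average' or 'monoisotopic'")
    mass = sum(table[aa] for aa in sequence) + water
    if cys_carbamidomethyl:
        mass += CARBAMIDOMETHYL * sequence.count("C")
    return mass


def net_charge(sequence: str, ph: float, pka: str | dict = "emboss") -> float:
    """Henderson-Hasselbalch net charge at a given pH."""
    sequence = _validate(sequence)
    table = PKA_SETS[pka] if isinstance(pka, str) else pka
    counts = {g: sequence.count(g) for g in "CDEHKRY"}
    counts["Nterm"] = counts["Cterm"] = 1
    pos = sum(
        counts.get(g, 0) / (1.0 + 10.0 ** (ph - table[g]))
        for g in POSITIVE if g in table
    )
    neg = sum(
        counts.get(g, 0) / (1.0 + 10.0 ** (table[g] - ph))
        for g in NEGATIVE if g in table
    )
    return pos - neg


def compute_pI(sequence: str, pka: str | dict = "emboss", tol: float = 1e-3) -> float:
    """Isoelectric point: the pH where the net charge crosses zero, found by
    bisection on [0, 14].  Termini are always ionizable, so the charge is
    strictly decreasing in pH and a unique root exists."""
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def aa_composition(records) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-protein residue fractions and, when both organs are present, a
    per-residue Welch t comparison between organ groups with BH adjustment.

    Returns ``(fractions, comparison)``; ``comparison`` is None when fewer
    than two proteins per organ are available.
    """
    aas = sorted(MONOISOTOPIC)
    rows = []
    for rec in records:
        seq = _validate(rec.sequence)
        n = len(seq)
        rows.append(
            {"accession": rec.accession, "organ": rec.organ,
             **{aa: seq.count(aa) / n for aa in aas}}
        )
    fractions = pd.DataFrame(rows).set_index("accession")

    organs = fractions["organ"].unique()
    if len(organs) < 2:
        return fractions, None
    a = fractions[fractions["organ"] == organs[0]][aas]
    b = fractions[fractions["organ"] == organs[1]][aas]
    if len(a) < 2 or len(b) < 2:
        return fractions, None
    t, p = stats.ttest_ind(a, b, equal_var=False)
    # identical groups give 0/0 -> no evidence of difference
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isnan(p), 1.0, p)
    p_adj = multipletests(p, method="fdr_bh")[1]
    comparison = pd.DataFrame(
        {"residue": aas, "t": t, "p_raw": p, "p_adj": p_adj,
         f"mean_{organs[0]}": a.mean().to_numpy(),
         f"mean_{organs[1]}": b.mean().to_numpy()}
    )
    return fractions, comparison


def positional_density(sequence: str, residue: str, n_bins: int = 20) -> np.ndarray:
    """Fraction of a target residue among residues falling in each bin of the
    relative sequence coordinate; position i maps to (i - 0.5) / length."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    sequence = _validate(sequence)
    coords = (np.arange(1, len(sequence) + 1) - 0.5) / len(sequence)
    bins = np.minimum((coords * n_bins).astype(int), n_bins - 1)
    is_target = np.array([aa == residue for aa in sequence])
    dens = np.zeros(n_bins)
    for b in range(n_bins):
        mask = bins == b
        if mask.any():
            dens[b] = is_target[mask].mean()
    return dens


@dataclass
class LadderCalibration:
    """Anchor points (Rf, MW kDa) from a protein ladder on the gel; migration
    increases as molecular weight decreases."""

    anchors: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValueError("at least two ladder anchors are required")
        rf = [a[0] for a in self.anchors]
        mw = [a[1] for a in self.anchors]
        if any(b <= a for a, b in zip(rf, rf[1:])):
            raise ValueError("Rf anchors must be strictly increasing")
        if any(b >= a for a, b in zip(mw, mw[1:])):
            raise ValueError("MW anchors must be strictly decreasing")


def mw_from_rf(rf: float, ladder: LadderCalibration) -> tuple[float, bool]:
    """Molecular weight (kDa) from gel migration by linear interpolation in
    (Rf, log10 MW) space.  Returns (MW, extrapolated_flag)."""
    rfs = np.array([a[0] for a in ladder.anchors])
    log_mw = np.log10([a[1] for a in ladder.anchors])
    extrapolated = bool(rf < rfs[0] or rf > rfs[-1])
    # np.interp clamps; extend linearly at the ends for flagged extrapolation
    if extrapolated:
        if rf < rfs[0]:
            slope = (log_mw[1] - log_mw[0]) / (rfs[1] - rfs[0])
            val = log_mw[0] + slope * (rf - rfs[0])
        else:
            slope = (log_mw[-1] - log_mw[-2]) / (rfs[-1] - rfs[-2])
            val = log_mw[-1] + slope * (rf - rfs[-1])
    else:
        val = float(np.interp(rf, rfs, log_mw))
    return float(10.0 ** val), extrapolated


def congruence(predicted, observed) -> tuple[float, float]:
    """Pearson correlation between predicted and gel-observed values with a
    two-sided t-based p-value."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or len(predicted) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(predicted) == 0 or np.std(observed) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(predicted, observed)
    return float(r), float(p)


def tryptic_digest(sequence: str, missed_cleavages: int = 2) -> list[str]:
    """In-silico trypsin digestion: cleave C-terminal to K or R unless the
    next residue is P; report all peptides spanning at most
    ``missed_cleavages`` internal sites, ordered by start position."""
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    sequence = _validate(sequence)
    cut_after = [
        i for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]
    bounds = [0] + [i + 1 for i in cut_after] + [len(sequence)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(bounds))):
            peptides.append((bounds[i], sequence[bounds[i]:bounds[j]]))
    peptides.sort(key=lambda t: (t[0], len(t[1])))
    return [p for _, p in peptides]


def peptide_masses(
    peptides: list[str],
    protonated: bool = False,
    cys_carbamidomethyl: bool = True,
    met_oxidation: bool = False,
) -> list[float]:
    """Monoisotopic peptide masses for MS1 fingerprint matching.

    MALDI MS1 peaks are singly protonated; pass ``protonated=True`` for
    [M+H]+ values.  Variable Met oxidation, when enabled, adds one extra
    candidate mass per oxidizable Met count.
    """
    masses: list[float] = []
    for pep in peptides:
        base = compute_mw(pep, kind="monoisotopic",
                          cys_carbamidomethyl=cys_carbamidomethyl)
        variants = [base]
        if met_oxidation:
            variants += [base + MET_OXIDATION * k
                         for k in range(1, pep.count("M") + 1)]
        masses.extend(variants)
    if protonated:
        masses = [m + PROTON for m in masses]
    return masses


def filter_autolysis(
    peaks: list[float],
    contaminant_masses: list[float],
    tolerance_da: float = 0.8,
) -> tuple[list[float], list[tuple[float, float]]]:
    """Remove MS1 peaks within +/- tolerance of any protease-autolysis mass.

    Returns (kept peaks, removal log of (peak, matched contaminant mass)).
    """
    if tolerance_da <= 0:
        raise ValueError("tolerance must be positive")
    contaminants = np.asarray(sorted(contaminant_masses), dtype=float)
    kept: list[float] = []
    removed: list[tuple[float, float]] = []
    for peak in peaks:
        if contaminants.size:
            i = int(np.argmin(np.abs(contaminants - peak)))
            if abs(contaminants[i] - peak) <= tolerance_da:
                removed.append((peak, float(contaminants[i])))
                continue
        kept.append(peak)
    return kept, removed


def protein_property_table(records) -> pd.DataFrame:
    """Summary TSV payload: accession, organ, length, average MW (kDa), pI."""
    rows = []
    for rec in records:
        rows.append(
            {
                "accession": rec.accession,
                "organ": rec.organ,
                "length": len(rec.sequence),
                "mw_kda": compute_mw(rec.sequence, "average") / 1000.0,
                "pI": compute_pI(rec.sequence),
                "lysine_fraction": rec.sequence.count("K") / len(rec.sequence),
            }
        )
    return pd.DataFrame(rows)
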