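"""Protein physicochemistry over the synthetic identifications.

Deduplicates the sequences, computes molecular weight, isoelectric point,
residue composition (with the shoot-vs-root Welch comparison), lysine
positional density, and checks the congruence of sequence-predicted versus
gel-ladder (Rf) molecular weights.  Also demonstrates the MS1 autolysis
filter with the bundled synthetic protease.

Reads results/synthetic/; writes results/proteochem/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from digeflow import io, load_synthetic_trypsin, protchem, simulate

IN = Path("results/synthetic")
OUT = Path("results/proteochem")
SEED = 2025

LADDER = protchem.LadderCalibration(
    [(0.1, 180.0), (0.3, 70.0), (0.5, 35.0), (0.7, 15.0), (0.9, 5.0)])


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = []
    for organ in io.ORGANS:
        records += io.read_protein_fasta(IN / f"{organ}_proteins.fasta", organ=organ)
    records = io.dedup_sequences(records)
    props = protchem.protein_property_table(records)
    props.to_csv(OUT / "properties.tsv", sep="\t", index=False)
    by_organ = props.groupby("organ")[["mw_kda", "pI"]].mean()
    print(f"{len(records)} unique proteins; mean MW/pI by organ:\n{by_organ.round(2)}")

    fractions, comparison = protchem.aa_composition(records)
    fractions.to_csv(OUT / "composition.tsv", sep="\t")
    if comparison is not None:
        comparison.to_csv(OUT / "composition_organ_comparison.tsv", sep="\t",
                          index=False)
        flagged = comparison[comparison.p_adj < 0.05]["residue"].tolist()
        print(f"residues differing between organs at BH p<0.05: {flagged or 'none'}")

    dens = pd.DataFrame(
        {r.accession: protchem.positional_density(r.sequence, "K", 20)
         for r in records})
    dens.index.name = "bin"
    dens.to_csv(OUT / "lysine_positional_density.tsv", sep="\t")

    # congruence of predicted MW vs the Rf-ladder estimate (simulated gels:
    # true migration from predicted MW plus measurement noise)
    rng = np.random.default_rng(SEED)
    predicted = props["mw_kda"].to_numpy()
    rf_anchor = np.interp(np.log10(predicted),
                          np.log10([a[1] for a in LADDER.anchors][::-1]),
                          [a[0] for a in LADDER.anchors][::-1])
    observed_rf = np.clip(rf_anchor + rng.normal(0, 0.01, len(predicted)), 0.1, 0.9)
    observed = np.array([protchem.mw_from_rf(rf, LADDER)[0] for rf in observed_rf])
    r, p = protchem.congruence(predicted, observed)
    pd.DataFrame({"accession": props["accession"], "mw_predicted_kda": predicted,
                  "rf": observed_rf, "mw_gel_kda": observed}).to_csv(
        OUT / "mw_congruence.tsv", sep="\t", index=False)
    print(f"predicted vs gel MW: Pearson r={r:.3f} (p={p:.2e})")

    # MS1 fingerprint of the first protein contaminated by protease autolysis
    protease = io.ProteinRecord("PROT_SYN", load_synthetic_trypsin())
    peaks = simulate.generate_peaklist(records[0], contaminant=protease,
                                       noise_peaks=10, seed=SEED)
    contaminant_masses = protchem.peptide_masses(
        protchem.tryptic_digest(protease.sequence))
    kept, removed = protchem.filter_autolysis(peaks, contaminant_masses)
    pd.Series(kept, name="mz").to_csv(OUT / "peaklist_filtered.tsv", sep="\t",
                                      index=False)
    print(f"autolysis filter: {len(peaks)} peaks -> {len(kept)} kept, "
          f"{len(removed)} removed")


if __name__ == "__main__":
    main()
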