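"""Generate the synthetic study dataset.

Emulates the experimental design — two organs (shoot, root), three
conditions (control, anoxia, re-aeration), three biological replicates —
with 15 spots per trajectory group per organ (60 spots/organ, inside the
40-90 spots/organ range of real gels), plus synthetic protein sequences and
promoters with planted family-labelled binding sites.

Writes results/synthetic/.
"""

from pathlib import Path

from Bio import SeqIO

from digeflow import io, simulate

SEED = 2025
OUT = Path("results/synthetic")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for i, organ in enumerate(io.ORGANS):
        design = simulate.default_design(organ)
        table, truth = simulate.generate_spot_table(15, design, seed=SEED + i)
        io.write_spot_table(table, OUT / f"{organ}_spots.tsv")
        io.write_sample_sheet(design, OUT / f"{organ}_samples.tsv")
        truth.to_csv(OUT / f"{organ}_truth.tsv", sep="\t")
        print(f"{organ}: {table.n_spots} spots x {len(design)} samples "
              f"(groups 1-4, 15 spots each)")

        proteins = simulate.generate_proteins(12 if organ == "shoot" else 8,
                                              seed=SEED + 10 + i, organ=organ)
        io.write_protein_fasta(proteins, OUT / f"{organ}_proteins.fasta")
        print(f"{organ}: {len(proteins)} synthetic protein sequences")

    planted = [
        simulate.PlantedMotifSpec("WRKY", "TTGACC", 2, condition_group="anoxia"),
        simulate.PlantedMotifSpec("ERF", "AGCCGCC", 1, condition_group="reaeration"),
        simulate.PlantedMotifSpec("TBP", "TATAAAT", 1, condition_group="control"),
    ]
    recs, truth = simulate.generate_promoters(40, 500, at_fraction=0.6,
                                              planted=planted, seed=SEED + 20)
    SeqIO.write(recs, str(OUT / "promoters.fasta"), "fasta")
    truth.to_csv(OUT / "promoters_truth.tsv", sep="\t", index=False)
    print(f"promoters: {len(recs)} x 500 nt, {len(truth)} planted sites "
          f"(WRKY x2, ERF, TBP per gene)")


if __name__ == "__main__":
    main()
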