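"""digeflow: post-acquisition analysis of 2D-DIGE spot intensities.

Covers the in-silico portion of a three-condition (control / anoxia /
re-aeration) gel-proteomics experiment: spot-table IO, synthetic data with
planted structure, normalization and differential statistics (including an
empirical-Bayes moderated F test), clustering with partition-concordance
scores, abundance-trajectory classification, protein physicochemistry, and
promoter binding-site summaries.
"""

from importlib import resources

import pandas as pd

__version__ = "0.1.0"

__all__ = ["load_annotated_trajectories", "load_synthetic_trypsin"]


def load_annotated_trajectories() -> pd.DataFrame:
    """The 21 significant, annotated proteins (13 shoot, 8 root) with
    per-condition mean intensities encoding their published qualitative
    abundance patterns on a common arbitrary scale."""
    with resources.files("digeflow.data").joinpath("annotated_trajectories.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_synthetic_trypsin() -> str:
    """A synthetic trypsin-like protease sequence (stand-in for a reference
    trypsin) used to exercise the autolysis-peak filter."""
    with resources.files("digeflow.data").joinpath("trypsin_synthetic.fasta").open() as fh:
        lines = fh.read().splitlines()
    return "".join(l for l in lines if not l.startswith(">"))
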