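"""Shared fixtures: consensus tables, small simulated ensembles and a toy
annotation/genome pair for extraction tests.  All fixture data are built
programmatically."""

from __future__ import annotations

import textwrap

import numpy as np
import pytest

from splicesel.simulate import SimParams, simulate_triplet_ensemble
from splicesel.sites import ConsensusTable

# --- toy genome -----------------------------------------------------------
# chr1 (plus strand): exon1 [0,30) | intron1 [30,70) | exon2 [70,100) |
# intron2 [100,140) | exon3 [140,170).  Introns are GT..AG with a 24-base
# polypyrimidine-ish tail; exons end in CAG / start with G so every site is
# canonical.  chr2 is the reverse complement of chr1 with mirrored
# coordinates, exercising the minus-strand path.

EXON1 = "ATGGCAGCTGACCTGATCGATCGATACCAG"
INTRON_TAIL = "TTTTTCTTTTTCTTTTTCCACAG"  # 23 bases ending in CAG
INTRON1 = "GTAAGT" + "CGCATCGCAT" + "T" + INTRON_TAIL
EXON2 = "G" + "TTCGATCGATGCATGCATGCATGCAT"[:26] + "CAG"
INTRON2 = "GTAAGT" + "ACGTACGTAC" + "T" + INTRON_TAIL
EXON3 = "G" + "CCTGATCGGATCGATTACGATCGATACGG"[:29]
CHR1 = EXON1 + INTRON1 + EXON2 + INTRON2 + EXON3

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


CHR2 = revcomp(CHR1)
L = len(CHR1)


def _gff() -> str:
    # chr1 plus-strand gene with a cassette exon2 (absent from t2); chr2
    # carries the mirrored minus-strand copy of t1.
    def exon(chrom, start0, end0, strand, tx, gene):
        return (
            f"{chrom}\ttoy\texon\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t"
            f"ID=e{chrom}{start0};Parent={tx}\n"
        )

    lines = ["##gff-version 3\n"]
    lines.append(
        "chr1\ttoy\tgene\t1\t170\t.\t+\t.\tID=g1;gene_id=g1\n"
    )
    for tx in ("t1", "t2"):
        lines.append(
            f"chr1\ttoy\ttranscript\t1\t170\t.\t+\t.\tID={tx};Parent=g1;"
            f"gene_id=g1;transcript_type=protein_coding\n"
        )
    for a, b in ((0, 30), (70, 100), (140, 170)):
        lines.append(exon("chr1", a, b, "+", "t1", "g1"))
    for a, b in ((0, 30), (140, 170)):
        lines.append(exon("chr1", a, b, "+", "t2", "g1"))
    lines.append("chr2\ttoy\tgene\t1\t170\t.\t-\t.\tID=g2;gene_id=g2\n")
    lines.append(
        "chr2\ttoy\ttranscript\t1\t170\t.\t-\t.\tID=t3;Parent=g2;gene_id=g2;"
        "transcript_type=lincRNA\n"
    )
    for a, b in ((0, 30), (70, 100), (140, 170)):
        lines.append(exon("chr2", L - b, L - a, "-", "t3", "g2"))
    return "".join(lines)


@pytest.fixture(scope="session")
def toy_genome() -> dict[str, str]:
    return {"chr1": CHR1, "chr2": CHR2}


@pytest.fixture(scope="session")
def toy_gff(tmp_path_factory) -> str:
    path = tmp_path_factory.mktemp("toy") / "toy.gff3"
    path.write_text(_gff())
    return str(path)


@pytest.fixture(scope="session")
def toy_fasta(tmp_path_factory, toy_genome) -> str:
    path = tmp_path_factory.mktemp("toy") / "toy.fa"
    with open(path, "w") as fh:
        for name, seq in toy_genome.items():
            fh.write(f">{name}\n{seq}\n")
    return str(path)


@pytest.fixture(scope="session")
def consensus() -> ConsensusTable:
    return ConsensusTable.default()


@pytest.fixture(scope="session")
def small_selected_ensemble():
    """10k donor sites under homogeneous Cn advantage (S = -2)."""
    return simulate_triplet_ensemble(
        SimParams(n_sites=10000, site_type="donor", S_profile=-2.0, seed=42)
    )


@pytest.fixture(scope="session")
def small_neutral_ensemble():
    return simulate_triplet_ensemble(
        SimParams(n_sites=10000, site_type="donor", S_profile=0.0, seed=43)
    )
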