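"""Splice-site coordinates, consensus tables, extraction and classification.

Conventions
-----------
Positions within a splice site are numbered relative to the exon-intron
boundary in the transcribed direction, with no position 0:

* donor (5') site: offsets -3..-1 are the last three exonic bases, +1..+6
  the first six intronic bases; +1,+2 carry the invariant GT.
* acceptor (3') site: offsets -24..-1 are the last intronic bases, +1 the
  first exonic base; -2,-1 carry the invariant AG.

At each non-invariant position the one or two most frequent nucleotides in
the genome form the consensus (Cn) set; all others are nonconsensus (Nc).
Position -4 of the acceptor has no usable consensus and is excluded from
scoring.  Genomic coordinates are handled internally as 0-based half-open;
the signed offsets above are the only coordinates exposed to users.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
NUC_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}
COMPLEMENT = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")

DONOR = "donor"
ACCEPTOR = "acceptor"

DONOR_OFFSETS: tuple[int, ...] = tuple(range(-3, 0)) + tuple(range(1, 7))
ACCEPTOR_OFFSETS: tuple[int, ...] = tuple(range(-24, 0)) + (1,)

#: invariant canonical dinucleotides, offset -> base on the transcribed strand
DONOR_INVARIANT = {1: "G", 2: "T"}
ACCEPTOR_INVARIANT = {-2: "A", -1: "G"}

#: acceptor position where no consensus can be established
ACCEPTOR_NO_CONSENSUS = (-4,)


class Role(str, Enum):
    EXONIC = "exonic"
    INTRONIC = "intronic"
    INVARIANT = "invariant"
    NO_CONSENSUS = "no_consensus"


def site_offsets(site_type: str) -> tuple[int, ...]:
    if site_type == DONOR:
        return DONOR_OFFSETS
    if site_type == ACCEPTOR:
        return ACCEPTOR_OFFSETS
    raise ValueError(f"unknown site type: {site_type!r}")


def invariant_bases(site_type: str) -> dict[int, str]:
    return dict(DONOR_INVARIANT if site_type == DONOR else ACCEPTOR_INVARIANT)


def position_role(site_type: str, offset: int) -> Role:
    """Structural role of a splice-site position (deterministic lookup)."""
    if offset not in site_offsets(site_type):
        raise ValueError(f"offset {offset} outside the {site_type} range")
    if site_type == DONOR:
        if offset in DONOR_INVARIANT:
            return Role.INVARIANT
        return Role.EXONIC if offset < 0 else Role.INTRONIC
    if offset in ACCEPTOR_INVARIANT:
        return Role.INVARIANT
    if offset in ACCEPTOR_NO_CONSENSUS:
        return Role.NO_CONSENSUS
    return Role.EXONIC if offset > 0 else Role.INTRONIC


@dataclass
class SpliceSiteRecord:
    """One donor or acceptor site with per-species sequences over its offsets.

    ``seq_by_species`` maps a species name to the sequence over the offset
    range on the transcribed strand; the reference species is keyed ``ref``
    by convention.
    """

    site_id: str
    site_type: str
    seq_by_species: dict[str, str]
    coding_class: str = "coding"
    splicing_class: str = "constitutive"
    strength_class: str | None = None
    strength_fraction: float | None = None
    chrom: str | None = None
    strand: str | None = None
    boundary: int | None = None  # 0-based coord of the first intronic base

    @property
    def offsets(self) -> tuple[int, ...]:
        return site_offsets(self.site_type)

    def __post_init__(self) -> None:
        n = len(self.offsets)
        for sp, seq in self.seq_by_species.items():
            if len(seq) != n:
                raise ValueError(
                    f"{self.site_id}: sequence for {sp!r} has length "
                    f"{len(seq)}, expected {n}"
                )

    def base(self, species: str, offset: int) -> str:
        return self.seq_by_species[species][self.offsets.index(offset)]


class ConsensusTable:
    """Per (site_type, offset) consensus nucleotide sets and position roles.

    Cn sets are stored only for positions whose role is exonic or intronic;
    invariant and no-consensus positions never carry a Cn set, regardless of
    the frequencies a table was derived from.
    """

    def __init__(self, cn: Mapping[tuple[str, int], Iterable[str]]):
        self._cn: dict[tuple[str, int], frozenset[str]] = {}
        for (site_type, offset), nucs in cn.items():
            role = position_role(site_type, offset)
            if role in (Role.INVARIANT, Role.NO_CONSENSUS):
                continue  # forced roles override any supplied set
            s = frozenset(str(n).upper() for n in nucs)
            if not s:
                continue
            if not s <= set(NUCLEOTIDES):
                raise ValueError(f"invalid consensus set {s} at {site_type} {offset}")
            if len(s) > 2:
                raise ValueError(
                    f"consensus set at {site_type} {offset} has {len(s)} > 2 members"
                )
            self._cn[(site_type, offset)] = s

    def cn(self, site_type: str, offset: int) -> frozenset[str] | None:
        """Consensus set, or None for invariant/no-consensus/undefined."""
        position_role(site_type, offset)  # range check
        return self._cn.get((site_type, offset))

    def nc(self, site_type: str, offset: int) -> frozenset[str]:
        cn = self.cn(site_type, offset)
        if cn is None:
            raise ValueError(f"no consensus defined at {site_type} {offset}")
        return frozenset(NUCLEOTIDES) - cn

    def role(self, site_type: str, offset: int) -> Role:
        return position_role(site_type, offset)

    def scored_offsets(self, site_type: str) -> tuple[int, ...]:
        """Offsets with exonic/intronic role and a defined Cn set."""
        return tuple(
            o
            for o in site_offsets(site_type)
            if position_role(site_type, o) in (Role.EXONIC, Role.INTRONIC)
            and (site_type, o) in self._cn
        )

    def cn_mask(self, site_type: str) -> np.ndarray:
        """Boolean (n_offsets, 4) matrix: True where nucleotide is Cn."""
        offs = site_offsets(site_type)
        mask = np.zeros((len(offs), 4), dtype=bool)
        for j, o in enumerate(offs):
            cn = self._cn.get((site_type, o))
            if cn:
                for nuc in cn:
                    mask[j, NUC_INDEX[nuc]] = True
        return mask

    def __eq__(self, other) -> bool:
        return isinstance(other, ConsensusTable) and self._cn == other._cn

    @classmethod
    def default(cls) -> "ConsensusTable":
        """Canonical U2 donor/acceptor consensus (configuration default).

        Donor MAG|GTRAGT and acceptor (Y)nCAG|G.  Any table derived from an
        actual nucleotide frequency table overrides this.
        """
        cn: dict[tuple[str, int], set[str]] = {
            (DONOR, -3): {"A", "C"},
            (DONOR, -2): {"A"},
            (DONOR, -1): {"G"},
            (DONOR, 3): {"A", "G"},
            (DONOR, 4): {"A"},
            (DONOR, 5): {"G"},
            (DONOR, 6): {"T"},
            (ACCEPTOR, -3): {"C"},
            (ACCEPTOR, 1): {"G"},
        }
        for o in range(-24, -4):
            cn[(ACCEPTOR, o)] = {"C", "T"}
        return cls(cn)


def derive_consensus(
    freq_table: Mapping[tuple[str, int], Mapping[str, float]],
    secondary_threshold: float = 0.35,
) -> ConsensusTable:
    """Derive a ConsensusTable from per-position nucleotide frequencies.

    The most frequent nucleotide is always Cn; the second most frequent is
    included iff its (normalized) frequency is at least
    ``secondary_threshold``.  The result is invariant to rescaling of the
    input frequencies.  Ties at an inclusion boundary are resolved
    alphabetically and logged.
    """
    cn: dict[tuple[str, int], set[str]] = {}
    for key, freqs in freq_table.items():
        site_type, offset = key
        if position_role(site_type, offset) in (Role.INVARIANT, Role.NO_CONSENSUS):
            continue
        total = float(sum(freqs.get(n, 0.0) for n in NUCLEOTIDES))
        if total <= 0:
            raise ValueError(f"non-positive frequency total at {key}")
        norm = {n: freqs.get(n, 0.0) / total for n in NUCLEOTIDES}
        order = sorted(norm, key=lambda n: (-norm[n], n))
        top, second = order[0], order[1]
        if norm[top] == norm[second]:
            log.warning(
                "tie for the top nucleotide at %s %+d resolved alphabetically",
                site_type,
                offset,
            )
        members = {top}
        if norm[second] >= secondary_threshold:
            third = order[2]
            if norm[second] == norm[third]:
                log.warning(
                    "tie at the secondary-Cn threshold at %s %+d resolved "
                    "alphabetically",
                    site_type,
                    offset,
                )
            members.add(second)
        cn[key] = members
    return ConsensusTable(cn)


def frequency_table(
    records: Sequence[SpliceSiteRecord], species: str = "ref"
) -> dict[tuple[str, int], dict[str, float]]:
    """Per (site_type, offset) nucleotide frequencies of the given species."""
    counts: dict[tuple[str, int], dict[str, float]] = {}
    for rec in records:
        seq = rec.seq_by_species[species]
        for o, base in zip(rec.offsets, seq):
            if base not in NUC_INDEX:
                continue
            d = counts.setdefault((rec.site_type, o), {n: 0.0 for n in NUCLEOTIDES})
            d[base] += 1.0
    for key, d in counts.items():
        tot = sum(d.values())
        if tot > 0:
            for n in NUCLEOTIDES:
                d[n] /= tot
    return counts


def ss_strength(
    record: SpliceSiteRecord,
    consensus: ConsensusTable,
    species: str = "ref",
) -> float:
    """Fraction of scored positions occupied by a Cn nucleotide."""
    offs = consensus.scored_offsets(record.site_type)
    if not offs:
        raise ValueError(f"no scored offsets for {record.site_type}")
    hits = sum(
        1 for o in offs if record.base(species, o) in consensus.cn(record.site_type, o)
    )
    return hits / len(offs)


def assign_strength_classes(
    fractions: Sequence[float], labels: tuple[str, ...] = ("weak", "middle", "strong")
) -> tuple[list[str], list[float]]:
    """Split an ensemble of Cn fractions into near-equal tertiles.

    Records are ranked by fraction with a stable sort (ties broken by input
    order) and split into len(labels) contiguous groups of near-equal size.
    Returns the per-record class labels and the boundary fractions.
    """
    arr = np.asarray(fractions, dtype=float)
    n = arr.size
    order = np.argsort(arr, kind="stable")
    k = len(labels)
    edges = [round(i * n / k) for i in range(k + 1)]
    out = np.empty(n, dtype=object)
    bounds: list[float] = []
    for i, lab in enumerate(labels):
        idx = order[edges[i] : edges[i + 1]]
        out[idx] = lab
        if i < k - 1 and edges[i + 1] > 0:
            bounds.append(float(arr[order[edges[i + 1] - 1]]))
    return list(out), bounds


# ---------------------------------------------------------------------------
# extraction from annotation + genome + species alignments
# ---------------------------------------------------------------------------


def _revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def _load_fasta(source) -> dict[str, str]:
    if isinstance(source, Mapping):
        return {k: str(v) for k, v in source.items()}
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(source), "fasta")
    }


def _slice(seqs: dict[str, str], chrom: str, start: int, end: int, strand: str) -> str:
    """0-based half-open genomic slice on the transcribed strand."""
    if chrom not in seqs:
        raise ValueError(f"sequence {chrom!r} missing from FASTA input")
    s = seqs[chrom]
    if start < 0 or end > len(s):
        raise ValueError(f"region {chrom}:{start}-{end} outside genome bounds")
    piece = s[start:end].upper()
    return _revcomp(piece) if strand == "-" else piece


def _canonical(site_type: str, seq: str) -> bool:
    offs = site_offsets(site_type)
    inv = invariant_bases(site_type)
    return all(seq[offs.index(o)] == b for o, b in inv.items())


def _coding_class(attrs) -> str:
    for key in ("transcript_biotype", "transcript_type", "gene_biotype", "biotype"):
        if key in attrs:
            val = attrs[key]
            val = val[0] if isinstance(val, (list, tuple)) else val
            return "coding" if val == "protein_coding" else "noncoding"
    return "coding"


def parse_splice_sites(
    annotation,
    genome,
    alignments: Mapping[str, object] | None = None,
    min_exon: int = 3,
) -> list[SpliceSiteRecord]:
    """Extract donor/acceptor records from a GFF3/GTF annotation and FASTA.

    ``alignments`` maps species names (conventionally ``sister`` and
    ``outgroup``) to FASTA inputs aligned to the reference genome
    coordinates (same sequence names, same lengths, ``-`` for gaps).  Sites
    whose canonical dinucleotide is absent in any species are excluded;
    duplicate sites shared between transcripts are collapsed by genomic
    coordinate and strand.  Splicing class (constitutive/cassette) is
    inferred from transcript structure: an exon is constitutive iff it is
    present in every transcript of its gene.
    """
    import gffutils

    db = gffutils.create_db(
        str(annotation),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    ref = _load_fasta(genome)
    species = {name: _load_fasta(src) for name, src in (alignments or {}).items()}

    # exon -> constitutive? (present in every transcript of its gene)
    tx_of_gene: dict[str, list] = {}
    exons_of_tx: dict[str, list] = {}
    gene_of_tx: dict[str, str] = {}
    for tx in db.features_of_type(("transcript", "mRNA")):
        gene = tx.attributes.get("gene_id", [tx.id])[0]
        tx_of_gene.setdefault(gene, []).append(tx)
        gene_of_tx[tx.id] = gene
        exons_of_tx[tx.id] = sorted(
            db.children(tx, featuretype="exon"), key=lambda e: e.start
        )
    exon_sets = {
        gene: [
            {(e.seqid, e.start, e.end, e.strand) for e in exons_of_tx[t.id]}
            for t in txs
        ]
        for gene, txs in tx_of_gene.items()
    }

    def constitutive(gene: str, exon_key) -> bool:
        return all(exon_key in s for s in exon_sets[gene])

    records: dict[tuple, SpliceSiteRecord] = {}
    n_skipped_strand = n_noncanonical = n_short = 0
    for tx_id, exons in exons_of_tx.items():
        if len(exons) < 2:
            continue
        tx = db[tx_id]
        if tx.strand not in ("+", "-"):
            log.warning("transcript %s has unknown strand; skipped", tx_id)
            n_skipped_strand += 1
            continue
        strand = tx.strand
        gene = gene_of_tx[tx_id]
        coding = _coding_class(tx.attributes)
        chrom = exons[0].seqid
        # exon coordinates as 0-based half-open
        coords = [(e.start - 1, e.end) for e in exons]
        keys = [(e.seqid, e.start, e.end, e.strand) for e in exons]
        for i in range(len(coords) - 1):
            istart, iend = coords[i][1], coords[i + 1][0]  # intron, 0-based
            if iend - istart < 1:
                continue
            if strand == "+":
                pairs = [
                    (DONOR, istart - 3, istart + 6, istart, keys[i]),
                    (ACCEPTOR, iend - 24, iend + 1, iend, keys[i + 1]),
                ]
            else:
                pairs = [
                    (DONOR, iend - 6, iend + 3, iend, keys[i + 1]),
                    (ACCEPTOR, istart - 1, istart + 24, istart, keys[i]),
                ]
            for site_type, start, end, boundary, exon_key in pairs:
                need = 6 if site_type == DONOR else 24
                if iend - istart < need:
                    n_short += 1
                    continue
                dedup = (chrom, strand, boundary, site_type)
                if dedup in records:
                    continue
                seqs = {"ref": _slice(ref, chrom, start, end, strand)}
                for sp, data in species.items():
                    seqs[sp] = _slice(data, chrom, start, end, strand)
                if not all(_canonical(site_type, s) for s in seqs.values()):
                    n_noncanonical += 1
                    continue
                records[dedup] = SpliceSiteRecord(
                    site_id=f"{chrom}:{boundary}:{strand}:{site_type}",
                    site_type=site_type,
                    seq_by_species=seqs,
                    coding_class=coding,
                    splicing_class=(
                        "constitutive"
                        if constitutive(gene, exon_key)
                        else "cassette"
                    ),
                    chrom=chrom,
                    strand=strand,
                    boundary=boundary,
                )
    log.info(
        "extracted %d sites (%d non-canonical excluded, %d near short introns "
        "skipped, %d unknown-strand transcripts skipped)",
        len(records),
        n_noncanonical,
        n_short,
        n_skipped_strand,
    )
    return list(records.values())


# ---------------------------------------------------------------------------
# TSV site table round trip
# ---------------------------------------------------------------------------


def site_table(records: Sequence[SpliceSiteRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            "site_id": rec.site_id,
            "site_type": rec.site_type,
            "chrom": rec.chrom,
            "strand": rec.strand,
            "boundary": rec.boundary,
            "coding_class": rec.coding_class,
            "splicing_class": rec.splicing_class,
            "strength_class": rec.strength_class,
            "strength_fraction": rec.strength_fraction,
        }
        for sp, seq in rec.seq_by_species.items():
            row[f"seq_{sp}"] = seq
        rows.append(row)
    return pd.DataFrame(rows)


def write_site_table(records: Sequence[SpliceSiteRecord], path) -> None:
    site_table(records).to_csv(path, sep="\t", index=False)


def read_site_table(path) -> list[SpliceSiteRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    seq_cols = [c for c in df.columns if c.startswith("seq_")]
    out = []
    for _, row in df.iterrows():
        out.append(
            SpliceSiteRecord(
                site_id=str(row["site_id"]),
                site_type=str(row["site_type"]),
                seq_by_species={c[4:]: str(row[c]) for c in seq_cols},
                coding_class=str(row["coding_class"]),
                splicing_class=str(row["splicing_class"]),
                strength_class=(
                    None if pd.isna(row.get("strength_class")) else str(row["strength_class"])
                ),
                strength_fraction=(
                    None
                    if pd.isna(row.get("strength_fraction"))
                    else float(row["strength_fraction"])
                ),
                chrom=None if pd.isna(row.get("chrom")) else str(row["chrom"]),
                strand=None if pd.isna(row.get("strand")) else str(row["strand"]),
                boundary=None if pd.isna(row.get("boundary")) else int(row["boundary"]),
            )
        )
    return out
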