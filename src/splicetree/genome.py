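"""Gene models and splice-region classification.

Loads transcript structures from GTF (Ensembl/GENCODE attribute dialect) or
BED, derives introns as the gaps between consecutive exons, and classifies
genomic positions into splice-proximal region classes:

* donor: the last 3 exonic nt of an exon (transcript sense) plus the first
  6 nt of the following intron;
* acceptor: the first 3 exonic nt of an exon plus the last 12 nt of the
  preceding intron;
* exon / intron otherwise, intergenic outside every transcript.

Internally all intervals are 0-based half-open; VCF-style 1-based positions
are converted at the function boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import gffutils


class RegionClass(str, Enum):
    DONOR = "donor"
    ACCEPTOR = "acceptor"
    EXON = "exon"
    INTRON = "intron"
    INTERGENIC = "intergenic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: precedence used when one position maps to several transcripts
_PRECEDENCE = {
    RegionClass.DONOR: 0,
    RegionClass.ACCEPTOR: 1,
    RegionClass.EXON: 2,
    RegionClass.INTRON: 3,
    RegionClass.INTERGENIC: 4,
}


@dataclass(frozen=True)
class RegionConfig:
    """Widths of the donor/acceptor windows, in nucleotides.

    Defaults give a 3+6 donor window and a 3+12 acceptor window around each
    exon/intron boundary.
    """

    donor_exonic_nt: int = 3
    donor_intronic_nt: int = 6
    acceptor_exonic_nt: int = 3
    acceptor_intronic_nt: int = 12

    def __post_init__(self) -> None:
        for name in (
            "donor_exonic_nt",
            "donor_intronic_nt",
            "acceptor_exonic_nt",
            "acceptor_intronic_nt",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Transcript:
    """A transcript as a sorted list of 0-based half-open exon intervals."""

    transcript_id: str
    exons: list[tuple[int, int]]
    strand: str = "+"
    cds_flag: bool = False

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"({s0},{e0}) and ({s1},{e1})"
                )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, genomic order, half-open."""
        return [
            (e0[1], e1[0]) for e0, e1 in zip(self.exons, self.exons[1:])
        ]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript]
    biotype: str = "protein_coding"
    #: True when loaded from BED: no exon/intron structure, region-membership only
    structureless: bool = field(default=False)

    @property
    def span(self) -> tuple[int, int]:
        starts, ends = zip(*(t.span for t in self.transcripts))
        return min(starts), max(ends)


def load_gene_models(
    path: str | Path,
    biotype_filter: Iterable[str] | None = ("protein_coding",),
) -> list[GeneModel]:
    """Load gene models from a GTF or BED file.

    GTF exon records are grouped by gene/transcript attributes and genes not
    matching ``biotype_filter`` are dropped (pass ``None`` to keep all). BED
    intervals become single-exon, structureless region records that support
    subsetting but no donor/acceptor classification.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return _load_bed(path)
    return _load_gtf(path, biotype_filter)


def _load_bed(path: Path) -> list[GeneModel]:
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinate") from exc
            name = parts[3] if len(parts) > 3 else f"region_{lineno}"
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            models.append(
                GeneModel(
                    gene_id=name,
                    chrom=parts[0],
                    strand=strand,
                    transcripts=[Transcript(name, [(start, end)], strand)],
                    biotype="region",
                    structureless=True,
                )
            )
    if not models:
        warnings.warn(f"{path}: no intervals loaded", stacklevel=2)
    return models


def _load_gtf(path: Path, biotype_filter: Iterable[str] | None) -> list[GeneModel]:
    # gffutils skips malformed lines silently; validate the 9-column layout
    # up front so errors carry a line number.
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated GTF columns, "
                    f"got {len(fields)}"
                )
            if not fields[3].isdigit() or not fields[4].isdigit():
                raise ValueError(f"{path}:{lineno}: non-numeric GTF coordinates")
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils wraps parse failures opaquely
        raise ValueError(f"{path}: failed to parse as GTF/GFF: {exc}") from exc

    wanted = set(biotype_filter) if biotype_filter is not None else None
    # group exon features by (gene_id, transcript_id)
    genes: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        gene_id = _attr(feat, "gene_id")
        tx_id = _attr(feat, "transcript_id")
        if gene_id is None or tx_id is None:
            raise ValueError(
                f"{path}: exon at {feat.seqid}:{feat.start} lacks "
                "gene_id/transcript_id attributes"
            )
        biotype = (
            _attr(feat, "gene_biotype")
            or _attr(feat, "gene_type")
            or "protein_coding"
        )
        rec = genes.setdefault(
            gene_id,
            {"chrom": feat.seqid, "strand": feat.strand, "biotype": biotype, "tx": {}},
        )
        # gffutils uses 1-based inclusive; convert to 0-based half-open
        rec["tx"].setdefault(tx_id, []).append((feat.start - 1, feat.end))

    models = []
    for gene_id, rec in genes.items():
        if wanted is not None and rec["biotype"] not in wanted:
            continue
        transcripts = [
            Transcript(tx_id, sorted(exons), rec["strand"])
            for tx_id, exons in rec["tx"].items()
        ]
        models.append(
            GeneModel(gene_id, rec["chrom"], rec["strand"], transcripts, rec["biotype"])
        )
    if not models:
        warnings.warn(f"{path}: no gene models passed the biotype filter", stacklevel=2)
    return models


def _attr(feat, key: str) -> str | None:
    vals = feat.attributes.get(key)
    return vals[0] if vals else None


def classify_region(
    pos: int,
    transcript: Transcript,
    strand: str | None = None,
    cfg: RegionConfig = RegionConfig(),
) -> RegionClass:
    """Classify a 1-based genomic position relative to one transcript.

    Donor/acceptor windows take precedence over plain exon/intron. On the
    minus strand the windows mirror: the genomic-leftmost end of an exon is
    its donor side. When an intron is too short for both intronic windows,
    positions in the overlap are assigned to the nearer splice site (ties
    to the donor).
    """
    if pos < 1:
        raise ValueError(f"position {pos} is off the chromosome")
    strand = strand or transcript.strand
    p = pos - 1  # 0-based
    span = transcript.span
    if not (span[0] <= p < span[1]):
        return RegionClass.INTERGENIC

    exons = transcript.exons
    introns = transcript.introns

    for i, (s, e) in enumerate(exons):
        if s <= p < e:
            # donor-side exonic window exists only if an intron follows in
            # transcript sense; acceptor-side only if one precedes.
            if strand == "+":
                has_next = i < len(exons) - 1
                has_prev = i > 0
                in_donor = has_next and p >= e - cfg.donor_exonic_nt
                in_acceptor = has_prev and p < s + cfg.acceptor_exonic_nt
            else:
                has_next = i > 0  # transcript-sense next intron is genomic-left
                has_prev = i < len(exons) - 1
                in_donor = has_next and p < s + cfg.donor_exonic_nt
                in_acceptor = has_prev and p >= e - cfg.acceptor_exonic_nt
            if in_donor and in_acceptor:
                # tiny exon: nearer boundary wins, tie to donor
                if strand == "+":
                    d_don, d_acc = e - p, p - s + 1
                else:
                    d_don, d_acc = p - s + 1, e - p
                return RegionClass.DONOR if d_don <= d_acc else RegionClass.ACCEPTOR
            if in_donor:
                return RegionClass.DONOR
            if in_acceptor:
                return RegionClass.ACCEPTOR
            return RegionClass.EXON

    for s, e in introns:
        if s <= p < e:
            length = e - s
            if strand == "+":
                d_don = p - s + 1  # nt into the intron from the 5'SS
                d_acc = e - p  # nt from the 3'SS
            else:
                d_don = e - p
                d_acc = p - s + 1
            in_donor = d_don <= cfg.donor_intronic_nt
            in_acceptor = d_acc <= cfg.acceptor_intronic_nt
            if in_donor and in_acceptor:
                if length > cfg.donor_intronic_nt + cfg.acceptor_intronic_nt:
                    raise AssertionError("window overlap in a long intron")
                return RegionClass.DONOR if d_don <= d_acc else RegionClass.ACCEPTOR
            if in_donor:
                return RegionClass.DONOR
            if in_acceptor:
                return RegionClass.ACCEPTOR
            return RegionClass.INTRON

    raise AssertionError("position inside span but in no exon or intron")


def classify_position(
    pos: int,
    gene_models: Sequence[GeneModel],
    cfg: RegionConfig = RegionConfig(),
) -> tuple[RegionClass, dict[str, RegionClass]]:
    """Classify a position against every overlapping transcript.

    Returns the most splice-proximal class (donor/acceptor > exon > intron)
    and the per-transcript breakdown.
    """
    per_tx: dict[str, RegionClass] = {}
    best = RegionClass.INTERGENIC
    for gm in gene_models:
        for tx in gm.transcripts:
            if gm.structureless:
                s, e = tx.span
                rc = RegionClass.EXON if s <= pos - 1 < e else RegionClass.INTERGENIC
            else:
                rc = classify_region(pos, tx, gm.strand, cfg)
            if rc is not RegionClass.INTERGENIC:
                per_tx[tx.transcript_id] = rc
            if _PRECEDENCE[rc] < _PRECEDENCE[best]:
                best = rc
    return best, per_tx


def intron_context(
    pos: int, transcript: Transcript, strand: str | None = None
) -> tuple[tuple[int, int], int, int] | None:
    """Containing intron plus distances to both splice sites, or None.

    Distances are 1-based in transcript sense: a position at the first
    intronic base has distance_to_5prime_ss == 1; at the last intronic base
    distance_to_3prime_ss == 1. Exonic/intergenic positions return None.
    """
    strand = strand or transcript.strand
    p = pos - 1
    for s, e in transcript.introns:
        if s <= p < e:
            if strand == "+":
                return (s, e), p - s + 1, e - p
            return (s, e), e - p, p - s + 1
    return None


def nearest_splice_distances(
    pos: int, transcript: Transcript, strand: str | None = None
) -> tuple[int | None, int | None]:
    """Distance (nt, >=1) from ``pos`` to the nearest donor and acceptor site.

    The donor site anchor is the first intronic base of each intron in
    transcript sense; the acceptor anchor is its last intronic base. Returns
    (None, None) for single-exon transcripts.
    """
    strand = strand or transcript.strand
    p = pos - 1
    donors: list[int] = []
    acceptors: list[int] = []
    for s, e in transcript.introns:
        if strand == "+":
            donors.append(s)
            acceptors.append(e - 1)
        else:
            donors.append(e - 1)
            acceptors.append(s)
    if not donors:
        return None, None
    d_don = min(abs(p - d) for d in donors) + 1
    d_acc = min(abs(p - a) for a in acceptors) + 1
    return d_don, d_acc
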