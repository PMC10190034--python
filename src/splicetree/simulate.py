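"""Self-contained synthetic test universe for the consensus pipeline.

Generates a toy genome with multi-exon genes (canonical GT..AG introns,
donor consensus GTAAGT, a pyrimidine-rich AG-free acceptor tail with a
planted branchpoint adenosine 25 nt upstream of the 3'SS, and one embedded
SRSF1-consensus ESE per exon), plants variants in every splice region
class, simulates class-conditional external-tool scores with controllable
separation and region-dependent missingness, and labels variants through a
latent simulated ΔPSI thresholded at 10% — mirroring the labelling rule
used for functionally validated variants.

Everything is deterministic per seed; all outputs are plain text (FASTA,
GTF, VCF, TSV, BED) and are consumable by the other pipeline stages
unmodified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .ingest import TOOL_SCHEMAS
from .pwm import default_pwms
from .variants import Variant, decompose_complex

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_DONOR_CONSENSUS = "GTAAGT"
_TAIL_LEN = 42  # AG-free acceptor tail; last 44 intronic nt = tail + AG
_BP_TAIL_IDX = 19  # branchpoint adenosine at 25 nt from the 3'SS
_ESE_CONSENSUS = "CACACGA"  # matches the packaged SRSF1 stand-in matrix

_DEFAULT_N_VARIANTS = {"donor": 40, "acceptor": 40, "exon": 60, "intron": 60}

_DEFAULT_SEPARATION = {
    "spliceai": 0.55,
    "mmsplice": 2.5,
    "spliceogen": 0.45,
    "cadd": 12.0,
    "spidex": 2.5,
    "dbscsnv": 0.45,
    "branchpointer": 0.35,
}

#: per-tool, per-region probability that the tool does not score a variant.
#: Precomputed-around-splice-sites tools (SPIDEX, dbscSNV) are blind outside
#: donor/acceptor windows; MMSplice degrades in deep introns.
_DEFAULT_MISSINGNESS = {
    "spliceai": {"donor": 0.03, "acceptor": 0.03, "exon": 0.05, "intron": 0.10},
    "mmsplice": {"donor": 0.05, "acceptor": 0.05, "exon": 0.20, "intron": 0.70},
    "spliceogen": {"donor": 0.10, "acceptor": 0.10, "exon": 0.15, "intron": 0.25},
    "cadd": {"donor": 0.02, "acceptor": 0.02, "exon": 0.02, "intron": 0.05},
    "spidex": {"donor": 0.05, "acceptor": 0.05, "exon": 0.30, "intron": 1.0},
    "dbscsnv": {"donor": 0.05, "acceptor": 0.05, "exon": 1.0, "intron": 1.0},
    "branchpointer": {"donor": 1.0, "acceptor": 0.30, "exon": 1.0, "intron": 0.50},
}


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_genes: int = 16
    exons_per_gene: int = 4
    intron_length_range: tuple[int, int] = (120, 200)
    exon_length_range: tuple[int, int] = (80, 150)
    intergenic_length: int = 250
    n_variants: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_N_VARIANTS)
    )
    complex_fraction: float = 0.10
    effect_fraction: float = 0.65
    dpsi_effect_mean: float = 0.35
    dpsi_effect_sd: float = 0.15
    dpsi_null_sd: float = 0.03
    dpsi_label_threshold: float = 0.10
    tool_separation: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SEPARATION)
    )
    missingness: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {t: dict(m) for t, m in _DEFAULT_MISSINGNESS.items()}
    )
    u12_fraction: float = 0.08
    informative_sequence_features: bool = True
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if not 0 < self.dpsi_label_threshold < 1:
            raise ValueError("dpsi_label_threshold must be in (0, 1)")
        for name in ("complex_fraction", "effect_fraction", "u12_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.intron_length_range[0] < 60:
            raise ValueError("introns must be >= 60 nt for the planted structure")
        if self.exon_length_range[0] < 30:
            raise ValueError("exons must be >= 30 nt to host an ESE motif")


# ---------------------------------------------------------------------------
# genome layout


@dataclass
class IntronLayout:
    start: int  # genomic 0-based half-open
    end: int
    bp_genomic: int  # 0-based branchpoint position
    three_ss_pos1: int  # 1-based last intronic base (acceptor side)
    u12: bool = False


@dataclass
class GeneLayout:
    gene_id: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    introns: list[IntronLayout]
    motif_starts: list[int]  # genomic 0-based start of the embedded ESE


@dataclass
class GenomeLayout:
    chrom: str
    seq: str
    genes: list[GeneLayout]


def _rand_seq(rng: np.random.Generator, n: int, alphabet: str = _BASES) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def generate_genome_and_models(cfg: SyntheticConfig) -> GenomeLayout:
    """Build the toy chromosome and its gene layouts (deterministic)."""
    rng = np.random.default_rng(cfg.seed)
    pieces: list[str] = []
    genes: list[GeneLayout] = []
    cursor = 0
    for gi in range(cfg.n_genes):
        spacer = _rand_seq(rng, cfg.intergenic_length)
        pieces.append(spacer)
        cursor += len(spacer)
        strand = "+" if gi % 2 == 0 else "-"
        gstart = cursor

        # build the gene in transcript sense first
        seg_parts: list[str] = []
        sense_exons: list[tuple[int, int]] = []
        sense_introns: list[dict] = []
        sense_motifs: list[int] = []
        at = 0
        n_exons = cfg.exons_per_gene
        for ei in range(n_exons):
            elen = int(rng.integers(*cfg.exon_length_range))
            exon = list(_rand_seq(rng, elen))
            moff = elen // 2 - len(_ESE_CONSENSUS) // 2
            exon[moff : moff + len(_ESE_CONSENSUS)] = _ESE_CONSENSUS
            seg_parts.append("".join(exon))
            sense_exons.append((at, at + elen))
            sense_motifs.append(at + moff)
            at += elen
            if ei < n_exons - 1:
                ilen = int(rng.integers(*cfg.intron_length_range))
                body_len = ilen - len(_DONOR_CONSENSUS) - _TAIL_LEN - 2
                body = _rand_seq(rng, body_len)
                # AG-free pyrimidine-rich tail with ~20% A and a planted bp
                tail = list(
                    "".join(
                        rng.choice(["C", "T", "A"], p=[0.45, 0.35, 0.20])
                        for _ in range(_TAIL_LEN)
                    )
                )
                tail[_BP_TAIL_IDX] = "A"
                intron_seq = _DONOR_CONSENSUS + body + "".join(tail) + "AG"
                bp_sense = at + len(_DONOR_CONSENSUS) + body_len + _BP_TAIL_IDX
                sense_introns.append(
                    {"span": (at, at + ilen), "bp_sense": bp_sense}
                )
                seg_parts.append(intron_seq)
                at += ilen
        seg = "".join(seg_parts)
        L = len(seg)

        if strand == "-":
            pieces.append(_revcomp(seg))
            to_genomic = lambda t: gstart + L - 1 - t  # noqa: E731
            exons = sorted(
                (gstart + L - te, gstart + L - ts) for ts, te in sense_exons
            )
        else:
            pieces.append(seg)
            to_genomic = lambda t: gstart + t  # noqa: E731
            exons = [(gstart + ts, gstart + te) for ts, te in sense_exons]

        introns = []
        for intr in sense_introns:
            ts, te = intr["span"]
            g1, g2 = to_genomic(ts), to_genomic(te - 1)
            s, e = (g1, g2 + 1) if strand == "+" else (g2, g1 + 1)
            three_ss = e if strand == "+" else s + 1  # 1-based last intronic base
            introns.append(
                IntronLayout(
                    start=s,
                    end=e,
                    bp_genomic=to_genomic(intr["bp_sense"]),
                    three_ss_pos1=three_ss,
                    u12=bool(rng.random() < cfg.u12_fraction),
                )
            )
        introns.sort(key=lambda i: i.start)

        motifs = [
            to_genomic(m) if strand == "+" else to_genomic(m + len(_ESE_CONSENSUS) - 1)
            for m in sense_motifs
        ]
        genes.append(
            GeneLayout(
                gene_id=f"gene{gi + 1}",
                strand=strand,
                start=gstart,
                end=gstart + L,
                exons=exons,
                introns=introns,
                motif_starts=motifs,
            )
        )
        cursor += L
    pieces.append(_rand_seq(rng, cfg.intergenic_length))
    return GenomeLayout(cfg.chrom, "".join(pieces), genes)


def write_genome_files(layout: GenomeLayout, outdir: str | Path) -> dict[str, Path]:
    """Write genome.fa / models.gtf / branchpoints.tsv / u12.bed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{layout.chrom}\n")
        for i in range(0, len(layout.seq), 70):
            fh.write(layout.seq[i : i + 70] + "\n")

    gtf = outdir / "models.gtf"
    with open(gtf, "w") as fh:
        for g in layout.genes:
            attrs = (
                f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; '
                'gene_biotype "protein_coding";'
            )
            fh.write(
                f"{layout.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}"; gene_biotype "protein_coding";\n'
            )
            fh.write(
                f"{layout.chrom}\tsim\ttranscript\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{layout.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )

    bp = outdir / "branchpoints.tsv"
    with open(bp, "w") as fh:
        fh.write("chrom\tthree_ss\tbp_pos\n")
        for g in layout.genes:
            for intr in g.introns:
                fh.write(
                    f"{layout.chrom}\t{intr.three_ss_pos1}\t{intr.bp_genomic + 1}\n"
                )

    u12 = outdir / "u12.bed"
    with open(u12, "w") as fh:
        for g in layout.genes:
            for intr in g.introns:
                if intr.u12:
                    fh.write(f"{layout.chrom}\t{intr.start}\t{intr.end}\t{g.gene_id}\n")
    return {"fasta": fasta, "gtf": gtf, "branchpoints": bp, "u12": u12}


# ---------------------------------------------------------------------------
# variant planting


@dataclass
class PlantedVariant:
    variant: Variant
    region: str  # planted region class
    mechanism: str
    designated_positive: bool
    dpsi: float = 0.0
    label: bool = False


def _sense_base(layout: GenomeLayout, strand: str, genomic0: int) -> str:
    b = layout.seq[genomic0]
    return b if strand == "+" else b.translate(_COMPLEMENT)


def _mk_snv(layout, strand, genomic0, alt_sense) -> Variant | None:
    ref = layout.seq[genomic0]
    alt = alt_sense if strand == "+" else alt_sense.translate(_COMPLEMENT)
    if alt == ref:
        return None
    return Variant(layout.chrom, genomic0 + 1, ref, alt)


def _mk_mnv(layout, strand, g_lo, g_hi, alt_sense) -> Variant:
    """MNV over genomic [g_lo, g_hi); alt given in transcript sense."""
    ref = layout.seq[g_lo:g_hi]
    alt = alt_sense if strand == "+" else _revcomp(alt_sense)
    return Variant(layout.chrom, g_lo + 1, ref, alt)


def _mk_deletion(layout, del_start0, del_len) -> Variant:
    anchor = layout.seq[del_start0 - 1]
    ref = layout.seq[del_start0 - 1 : del_start0 + del_len]
    return Variant(layout.chrom, del_start0, ref, anchor)


def _intron_sense_pos(intr: IntronLayout, strand: str, k: int) -> int:
    """Genomic 0-based position of the k-th intronic base (1-based, sense)."""
    return intr.start + k - 1 if strand == "+" else intr.end - k


def _intron_d3_pos(intr: IntronLayout, strand: str, d3: int) -> int:
    """Genomic 0-based position d3 nt from the 3'SS (d3=1: last base)."""
    return intr.end - d3 if strand == "+" else intr.start + d3 - 1


def _candidate_slots(cfg: SyntheticConfig, layout: GenomeLayout):
    """Enumerate (region, polarity, mechanism, builder) planting slots."""
    pwm_srsf1 = next(p for p in default_pwms() if p.name == "SRSF1")
    worst_base = [
        _BASES[int(np.argmin(pwm_srsf1.weights[i]))] for i in range(pwm_srsf1.width)
    ]
    slots: dict[tuple[str, bool], list] = {
        (r, pol): [] for r in _DEFAULT_N_VARIANTS for pol in (True, False)
    }
    for g in layout.genes:
        st = g.strand
        for intr in g.introns:
            # --- donor ---
            for k in (1, 2):  # the GT itself
                g0 = _intron_sense_pos(intr, st, k)
                ref_sense = _sense_base(layout, st, g0)
                for alt in _BASES:
                    if alt != ref_sense:
                        slots[("donor", True)].append(
                            ("donor_site_loss", "snv", (st, g0, alt))
                        )
            lo = min(_intron_sense_pos(intr, st, 1), _intron_sense_pos(intr, st, 2))
            slots[("donor", True)].append(("donor_site_loss", "mnv", (st, lo, lo + 2, "CA")))
            for k in (3, 4, 5, 6):
                g0 = _intron_sense_pos(intr, st, k)
                ref_sense = _sense_base(layout, st, g0)
                for alt in _BASES:
                    if alt != ref_sense:
                        slots[("donor", False)].append(
                            ("donor_region_neutral", "snv", (st, g0, alt))
                        )
            # --- acceptor ---
            for d3 in (1, 2):  # the AG itself
                g0 = _intron_d3_pos(intr, st, d3)
                ref_sense = _sense_base(layout, st, g0)
                for alt in _BASES:
                    if alt != ref_sense:
                        slots[("acceptor", True)].append(
                            ("acceptor_site_loss", "snv", (st, g0, alt))
                        )
            lo = min(_intron_d3_pos(intr, st, 1), _intron_d3_pos(intr, st, 2))
            slots[("acceptor", True)].append(
                ("acceptor_site_loss", "mnv", (st, lo, lo + 2, "TC"))
            )
            for d3 in range(4, 13):
                g0 = _intron_d3_pos(intr, st, d3)
                ref_sense = _sense_base(layout, st, g0)
                alt = {"C": "T", "T": "C", "A": "C"}.get(ref_sense)
                if alt:
                    slots[("acceptor", False)].append(
                        ("acceptor_region_neutral", "snv", (st, g0, alt))
                    )
            # --- deep intron: AGEZ AG creation (positive); d3 > 12 keeps the
            # planted position outside the annotated acceptor window ---
            for d3 in range(13, 25):
                g0 = _intron_d3_pos(intr, st, d3)
                prev0 = _intron_d3_pos(intr, st, d3 + 1)
                if (
                    _sense_base(layout, st, prev0) == "A"
                    and _sense_base(layout, st, g0) in "CT"
                ):
                    slots[("intron", True)].append(
                        ("agez_ag_creation", "snv", (st, g0, "G"))
                    )
            # --- deep intron: minimal-intron deletion (positive) ---
            ilen = intr.end - intr.start
            if ilen - 40 > 0 and intr.start >= 1:
                # deletion starts 14 nt into the intron: outside both the
                # donor (6 nt) and acceptor (12 nt) windows
                slots[("intron", True)].append(
                    ("min_intron_deletion", "del", (intr.start + 13 + 1, ilen - 40))
                )
            # --- deep intron neutral (negative): body C<->T, outside AGEZ ---
            for d3 in range(46, min(ilen - 7, 46 + 30)):
                g0 = _intron_d3_pos(intr, st, d3)
                prev0 = _intron_d3_pos(intr, st, d3 + 1)
                ref_sense = _sense_base(layout, st, g0)
                if ref_sense in "CT" and _sense_base(layout, st, prev0) != "G":
                    slots[("intron", False)].append(
                        (
                            "deep_intron_neutral",
                            "snv",
                            (st, g0, "T" if ref_sense == "C" else "C"),
                        )
                    )
        # --- exons ---
        for (es, ee), mstart in zip(g.exons, g.motif_starts):
            w = len(_ESE_CONSENSUS)
            for i in range(w):
                g0 = mstart + i
                sense_i = i if st == "+" else w - 1 - i
                alt_sense = worst_base[sense_i]
                if alt_sense != _ESE_CONSENSUS[sense_i]:
                    slots[("exon", True)].append(
                        ("ese_disruption", "snv", (st, g0, alt_sense))
                    )
            # complex ESE hit: replace two central motif bases
            lo = mstart + 2
            sense_lo = 2 if st == "+" else w - 4  # sense indices of [lo, lo+2)
            alt_sense = worst_base[sense_lo] + worst_base[sense_lo + 1]
            slots[("exon", True)].append(("ese_disruption", "mnv", (st, lo, lo + 2, alt_sense)))
            # neutral exonic SNVs away from the motif and the splice windows
            for g0 in range(es + 4, ee - 4):
                if mstart - 7 <= g0 <= mstart + w + 6:
                    continue
                ref = layout.seq[g0]
                alt = {"A": "C", "C": "A", "G": "C", "T": "G"}[ref]
                slots[("exon", False)].append(("exon_neutral", "snv", (st, g0, alt)))
    return slots


def _build_variant(layout, kind, args) -> Variant | None:
    if kind == "snv":
        st, g0, alt_sense = args
        return _mk_snv(layout, st, g0, alt_sense)
    if kind == "mnv":
        st, lo, hi, alt_sense = args
        v = _mk_mnv(layout, st, lo, hi, alt_sense)
        return None if v.ref == v.alt else v
    if kind == "del":
        pos1, dlen = args
        return _mk_deletion(layout, pos1, dlen)
    raise AssertionError(kind)


def generate_variants(
    cfg: SyntheticConfig, layout: GenomeLayout
) -> list[PlantedVariant]:
    """Plant variants per region class and label them via latent ΔPSI.

    In informative mode, designated positives are planted at disruptive
    sites (canonical GT/AG hits, ESE-consensus disruptions, AGEZ
    AG-creations, minimal-intron deletions) and designated negatives at
    neutral sites, so the rule-based sequence features carry signal. With
    ``informative_sequence_features=False`` every variant is planted at a
    neutral site regardless of designation. The label is
    |ΔPSI| >= dpsi_label_threshold where designated positives draw ΔPSI
    from the effect distribution and the rest from the null.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    slots = _candidate_slots(cfg, layout)
    used: set[str] = set()
    planted: list[PlantedVariant] = []
    for region, n in cfg.n_variants.items():
        if region not in _DEFAULT_N_VARIANTS:
            raise ValueError(f"unknown region class {region!r}")
        n_pos = int(round(n * cfg.effect_fraction))
        for polarity, count in ((True, n_pos), (False, n - n_pos)):
            slot_polarity = polarity if cfg.informative_sequence_features else False
            pool = list(slots[(region, slot_polarity)])
            order = rng.permutation(len(pool))
            taken = 0
            for idx in order:
                if taken >= count:
                    break
                mech, kind, args = pool[idx]
                v = _build_variant(layout, kind, args)
                if v is None or v.key in used:
                    continue
                used.add(v.key)
                if polarity:
                    dpsi = min(
                        abs(rng.normal(cfg.dpsi_effect_mean, cfg.dpsi_effect_sd)), 1.0
                    )
                else:
                    dpsi = min(abs(rng.normal(0.0, cfg.dpsi_null_sd)), 1.0)
                planted.append(
                    PlantedVariant(
                        variant=v,
                        region=region,
                        mechanism=mech,
                        designated_positive=polarity,
                        dpsi=float(dpsi),
                        label=bool(dpsi >= cfg.dpsi_label_threshold),
                    )
                )
                taken += 1
            if taken < count:
                raise ValueError(
                    f"region capacity exhausted: needed {count} "
                    f"{'positive' if polarity else 'negative'} slots in {region!r}, "
                    f"found {taken}; enlarge the genome (n_genes/exons_per_gene)"
                )
    planted.sort(key=lambda p: (p.variant.pos, p.variant.ref, p.variant.alt))
    return planted


def write_variant_files(
    planted: Sequence[PlantedVariant],
    layout: GenomeLayout,
    outdir: str | Path,
    export_dpsi: bool = False,
) -> dict[str, Path]:
    """Write variants.vcf and truth.tsv (labels; ΔPSI only on request)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vcf_path = outdir / "variants.vcf"
    header = pysam.VariantHeader()
    header.contigs.add(layout.chrom, length=len(layout.seq))
    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for p in planted:
            v = p.variant
            out.write(
                out.new_record(contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt))
            )

    truth_path = outdir / "truth.tsv"
    rows = []
    for p in planted:
        row = {
            "key": p.variant.key,
            "chrom": p.variant.chrom,
            "pos": p.variant.pos,
            "ref": p.variant.ref,
            "alt": p.variant.alt,
            "region": p.region,
            "mechanism": p.mechanism,
            "label": "positive" if p.label else "negative",
        }
        if export_dpsi:
            row["dpsi"] = f"{p.dpsi:.6f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(truth_path, sep="\t", index=False)
    return {"vcf": vcf_path, "truth": truth_path}


# ---------------------------------------------------------------------------
# simulated external-tool scores


def _truncnorm(rng, mean, sd, lo, hi) -> float:
    for _ in range(64):
        x = rng.normal(mean, sd)
        if lo is None or hi is None:
            return float(x)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(rng.normal(mean, sd), lo), hi))


_MECH_CATEGORY = {
    "donor_site_loss": "ds_dl",
    "acceptor_site_loss": "ds_al",
    "agez_ag_creation": "ds_ag",
    "ese_disruption": "ds_al",
    "min_intron_deletion": "ds_al",
}


def _draw_tool_scores(rng, tool: str, label: bool, mechanism: str, sep: float) -> dict:
    """Class-conditional score draws.

    The *only* label dependence is a mean shift of ``sep`` on the
    mechanism-relevant column(s); with ``sep == 0`` positives and negatives
    are distributionally identical (null recovery property).
    """
    cols = TOOL_SCHEMAS[tool]
    shift = sep if label else 0.0
    out = {}
    if tool == "spliceai":
        hot = _MECH_CATEGORY.get(mechanism, "ds_ag")
        for c in cols:
            out[c] = _truncnorm(rng, 0.08 + (shift if c == hot else 0.0), 0.12, 0.0, 1.0)
    elif tool == "mmsplice":
        mean = shift * (1 if rng.random() < 0.5 else -1)
        out["delta_logit_psi"] = float(rng.normal(mean, 0.6))
    elif tool == "spliceogen":
        hot = "donor_gain" if "donor" in mechanism else "acceptor_gain"
        for c in cols:
            out[c] = _truncnorm(rng, 0.12 + (shift if c == hot else 0.0), 0.12, 0.0, 1.0)
    elif tool == "cadd":
        out["phred"] = _truncnorm(rng, 6.0 + shift, 4.0, 0.0, 99.0)
    elif tool == "spidex":
        out["dpsi_zscore"] = float(rng.normal(-shift, 1.0))
    elif tool == "dbscsnv":
        for c in cols:
            out[c] = _truncnorm(rng, 0.30 + shift, 0.15, 0.0, 1.0)
    elif tool == "branchpointer":
        out["prob"] = _truncnorm(rng, 0.35 + shift, 0.15, 0.0, 1.0)
    else:  # pragma: no cover
        raise AssertionError(tool)
    return out


def simulate_tool_scores(
    cfg: SyntheticConfig,
    planted: Sequence[PlantedVariant],
    layout: GenomeLayout,
) -> dict[str, pd.DataFrame]:
    """Class-conditional per-tool score tables with region missingness.

    SpliceAI- and MMSplice-style tools score the decomposition *parts* of
    complex variants (they only handle simple alleles), exercising the
    max-over-parts aggregation downstream. SPIDEX/dbscSNV score SNVs only.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    tables: dict[str, list[dict]] = {t: [] for t in TOOL_SCHEMAS}
    for p in planted:
        v = p.variant
        for tool in TOOL_SCHEMAS:
            sep = float(cfg.tool_separation.get(tool, 0.0))
            miss = float(cfg.missingness.get(tool, {}).get(p.region, 0.1))
            if tool in ("spidex", "dbscsnv") and v.vclass != "SNV":
                continue
            if v.is_complex and tool in ("spliceai", "mmsplice"):
                anchor = layout.seq[v.pos - 2]
                for part in decompose_complex(v, anchor):
                    if rng.random() < miss:
                        continue
                    row = {"chrom": part.chrom, "pos": part.pos,
                           "ref": part.ref, "alt": part.alt}
                    row.update(_draw_tool_scores(rng, tool, p.label, p.mechanism, sep))
                    tables[tool].append(row)
                continue
            if rng.random() < miss:
                continue
            row = {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt}
            row.update(_draw_tool_scores(rng, tool, p.label, p.mechanism, sep))
            tables[tool].append(row)

    out: dict[str, pd.DataFrame] = {}
    for tool, rows in tables.items():
        cols = ["chrom", "pos", "ref", "alt", *TOOL_SCHEMAS[tool]]
        df = pd.DataFrame(rows, columns=cols)
        df = df.drop_duplicates(subset=["chrom", "pos", "ref", "alt"])
        out[tool] = df.round(6)
    return out


def write_score_files(
    tables: Mapping[str, pd.DataFrame], outdir: str | Path
) -> dict[str, Path]:
    outdir = Path(outdir)
    paths = {}
    for tool, df in tables.items():
        p = outdir / f"scores_{tool}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[tool] = p
    return paths


def simulate_dataset(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the complete fixture set into ``outdir``; returns paths."""
    layout = generate_genome_and_models(cfg)
    paths = write_genome_files(layout, outdir)
    planted = generate_variants(cfg, layout)
    paths.update(write_variant_files(planted, layout, outdir))
    tables = simulate_tool_scores(cfg, planted, layout)
    paths.update(
        {f"scores_{t}": p for t, p in write_score_files(tables, outdir).items()}
    )
    return paths
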