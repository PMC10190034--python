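"""VCF reading/writing, allele normalization and the pipeline filters.

Site-level only: genotypes are ignored. Multi-allelic records are split,
shared allele prefixes/suffixes trimmed (minimal anchored representation),
and complex variants (MNV / simultaneous insertion-deletion) can be
decomposed into a pure deletion plus a pure insertion so that external
predictors that only score simple alleles can be applied to each part.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .genome import GeneModel

_VALID = set("ACGT")

#: INFO keys probed, in order, for a gnomAD-popmax-style allele frequency
AF_INFO_KEYS = ("gnomAD_PopMax_AF", "AF_popmax", "gnomad_popmax_af", "AF")


@dataclass(frozen=True)
class Variant:
    """A normalized allele change. ``pos`` is 1-based (VCF convention).

    Empty ``ref``/``alt`` strings are permitted only for unanchored
    decomposition parts; VCF-facing variants always carry an anchor base.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    af_popmax: float | None = None
    gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if set(allele) - _VALID:
                raise ValueError(
                    f"allele {allele!r} at {self.chrom}:{self.pos} contains "
                    "bases outside A/C/G/T"
                )
        if self.pos < 1:
            raise ValueError(f"position {self.pos} < 1")

    @property
    def vclass(self) -> str:
        r, a = len(self.ref), len(self.alt)
        if r == a == 1:
            return "SNV"
        if r == a:
            return "MNV"
        if r > a:
            if a == 0 or (a == 1 and self.alt == self.ref[0]):
                return "deletion"
            return "insdel"
        if r == 0 or (r == 1 and self.ref == self.alt[0]):
            return "insertion"
        return "insdel"

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def end(self) -> int:
        """1-based inclusive end of the reference span."""
        return self.pos + max(len(self.ref), 1) - 1

    @property
    def is_complex(self) -> bool:
        return self.vclass in ("MNV", "insdel")


@dataclass(frozen=True)
class FilterConfig:
    af_max: float = 0.01
    missing_af_passes: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.af_max <= 1.0:
            raise ValueError("af_max must be in [0, 1]")


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared prefix/suffix to the minimal anchored representation.

    The trailing shared suffix is removed first, then the leading shared
    prefix (advancing ``pos``), always leaving at least one base in each
    allele. Matches the representation used for score-table keys.
    """
    if ref == alt:
        raise ValueError("ref == alt")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def read_vcf(path: str | Path) -> list[Variant]:
    """Read a VCF (v4.x, plain or bgzipped) into normalized Variants.

    Multi-allelic records become one Variant per alt allele. Symbolic and
    spanning-deletion alleles are skipped. A gnomAD-popmax-style AF is
    parsed from the first matching INFO key in ``AF_INFO_KEYS``.
    """
    out: list[Variant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.ref is None or rec.alts is None:
                continue
            af = _parse_af(rec)
            for alt in rec.alts:
                if alt is None or alt == "*" or alt.startswith("<"):
                    continue
                if set(rec.ref.upper()) - _VALID or set(alt.upper()) - _VALID:
                    raise ValueError(
                        f"{path}: record {rec.chrom}:{rec.pos} has non-ACGT allele"
                    )
                pos, ref, a = normalize_alleles(rec.pos, rec.ref.upper(), alt.upper())
                out.append(Variant(rec.chrom, pos, ref, a, af_popmax=af))
    return out


def _parse_af(rec) -> float | None:
    for k in AF_INFO_KEYS:
        if k in rec.info:
            v = rec.info[k]
            if isinstance(v, tuple):
                v = v[0]
            if v is None:
                continue
            try:
                return float(v)
            except (TypeError, ValueError):
                continue
    return None


def filter_by_regions(
    variants: Iterable[Variant], gene_models: Sequence[GeneModel]
) -> list[Variant]:
    """Keep variants whose reference span intersects any gene span.

    Any overlap counts (a deletion straddling a gene boundary is kept).
    Retained variants are annotated with the overlapping gene ids.
    """
    trees: dict[str, IntervalTree] = {}
    for gm in gene_models:
        s, e = gm.span
        trees.setdefault(gm.chrom, IntervalTree()).addi(s, e, gm.gene_id)
    kept = []
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        hits = tree.overlap(v.pos - 1, v.end)  # 0-based half-open ref span
        if hits:
            kept.append(replace(v, gene_ids=tuple(sorted(h.data for h in hits))))
    return kept


def filter_by_af(
    variants: Iterable[Variant], cfg: FilterConfig = FilterConfig()
) -> list[Variant]:
    """Population-frequency filter: keep af_popmax <= af_max.

    Variants absent from the population database (missing AF) pass by
    default — absence implies rarity.
    """
    out = []
    for v in variants:
        if v.af_popmax is None:
            if cfg.missing_af_passes:
                out.append(v)
        elif v.af_popmax <= cfg.af_max:
            out.append(v)
    return out


def decompose_complex(v: Variant, anchor_base: str | None = None) -> list[Variant]:
    """Split an MNV/insdel into a pure deletion plus a pure insertion.

    Simple variants are returned unchanged as a single part. When
    ``anchor_base`` (the reference base immediately 5' of ``v.pos``) is
    supplied, parts are emitted in valid anchored VCF style at pos-1;
    otherwise unanchored empty-allele parts at ``v.pos`` are produced.
    Applying the deletion then the insertion to the reference sequence
    reproduces the alt haplotype of the original variant.
    """
    if not v.is_complex:
        return [v]
    if anchor_base is not None:
        if v.pos < 2:
            raise ValueError("cannot anchor a decomposition at position 1")
        anchor_base = anchor_base.upper()
        if anchor_base not in _VALID:
            raise ValueError(f"anchor base {anchor_base!r} is not A/C/G/T")
        deletion = Variant(v.chrom, v.pos - 1, anchor_base + v.ref, anchor_base)
        insertion = Variant(v.chrom, v.pos - 1, anchor_base, anchor_base + v.alt)
    else:
        deletion = Variant(v.chrom, v.pos, v.ref, "")
        insertion = Variant(v.chrom, v.pos, "", v.alt)
    return [deletion, insertion]


def apply_variant(seq: str, seq_start: int, v: Variant) -> str:
    """Apply ``v`` to ``seq`` (whose first base is 1-based ``seq_start``).

    Used by oracle-style checks and alt-context construction. Raises if the
    reference allele does not match the sequence.
    """
    off = v.pos - seq_start
    if off < 0 or off + len(v.ref) > len(seq):
        raise ValueError("variant outside the provided sequence")
    if seq[off : off + len(v.ref)].upper() != v.ref:
        raise ValueError(
            f"reference mismatch at {v.chrom}:{v.pos}: "
            f"sequence has {seq[off:off + len(v.ref)]!r}, variant ref {v.ref!r}"
        )
    return seq[:off] + v.alt + seq[off + len(v.ref) :]


# ---------------------------------------------------------------------------
# annotated output


def write_annotated_vcf(
    variants: Sequence[Variant],
    feature_table: pd.DataFrame,
    scores: dict[str, float],
    out_prefix: str | Path,
    config_hash: str = "",
    contigs: dict[str, int] | None = None,
) -> tuple[Path, Path]:
    """Write the scored call set as a VCF plus a flat TSV mirror.

    ``feature_table`` is indexed by variant key; its columns become
    ``INTROME_F_<name>`` INFO entries (floats rendered with %.6g, missing
    values omitted from INFO but kept as NA in the TSV). ``scores`` maps
    variant key to the final consensus score. Returns (vcf_path, tsv_path).
    """
    out_prefix = Path(out_prefix)
    vcf_path = out_prefix.with_suffix(".vcf")
    tsv_path = out_prefix.with_suffix(".tsv")

    header = pysam.VariantHeader()
    if config_hash:
        header.add_line(f"##splicetree_config_hash={config_hash}")
    seen_contigs = contigs or {}
    for v in variants:
        seen_contigs.setdefault(v.chrom, None)
    for name, length in seen_contigs.items():
        if length:
            header.contigs.add(name, length=length)
        else:
            header.contigs.add(name)
    header.info.add("INTROME_SCORE", 1, "String", "Consensus splice-impact score in [0,1]")
    header.info.add("INTROME_REGION", 1, "String", "Splice region class of the variant")
    feat_cols = list(feature_table.columns) if feature_table is not None else []
    for col in feat_cols:
        if col == "region":
            continue
        header.info.add(f"INTROME_F_{col}", 1, "String", f"Feature {col}")

    rows = []
    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            row: dict[str, object] = {
                "key": v.key, "chrom": v.chrom, "pos": v.pos,
                "ref": v.ref, "alt": v.alt, "vclass": v.vclass,
            }
            if v.key in scores:
                formatted = _fmt(scores[v.key])
                rec.info["INTROME_SCORE"] = formatted
                row["INTROME_SCORE"] = formatted
            else:
                row["INTROME_SCORE"] = "NA"
            if feature_table is not None and v.key in feature_table.index:
                feats = feature_table.loc[v.key]
                for col in feat_cols:
                    val = feats[col]
                    if col == "region":
                        rec.info["INTROME_REGION"] = str(val)
                        row["region"] = str(val)
                        continue
                    if val is None or (isinstance(val, float) and math.isnan(val)):
                        row[col] = "NA"
                        continue
                    formatted = _fmt(val)
                    rec.info[f"INTROME_F_{col}"] = formatted
                    row[col] = formatted
            out.write(rec)
            rows.append(row)

    tsv = pd.DataFrame(rows)
    with open(tsv_path, "w") as fh:
        if config_hash:
            fh.write(f"# splicetree_config_hash={config_hash}\n")
        tsv.to_csv(fh, sep="\t", index=False)
    return vcf_path, tsv_path


def _fmt(val) -> str:
    if isinstance(val, bool):
        return "1" if val else "0"
    if isinstance(val, (int,)) or (isinstance(val, float) and float(val).is_integer()):
        return str(int(val))
    return format(float(val), ".6g")
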