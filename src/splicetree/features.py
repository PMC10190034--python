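"""Bespoke splice features and feature-vector assembly.

Beyond the external predictor scores, the consensus model consumes a set of
rule-based sequence features capturing known splicing biology:

* ESE/ESS PWM deltas (see :mod:`splicetree.pwm`);
* creation/removal of AG or GT dinucleotides by the variant;
* membership of the AG exclusion zone (AGEZ) — the stretch between the
  branchpoint and the acceptor AG that is normally AG-free; an AG
  introduced there can act as a cryptic acceptor, and one introduced
  within 15 nt of the branchpoint instead promotes exon skipping;
* U12 (minor spliceosome) intron membership;
* intronic deletions that would shrink an intron below the ~45 nt minimum
  the spliceosome requires;
* region class and distances to the nearest donor/acceptor sites.

Missing values are explicit (None / NaN); nothing is silently imputed —
the downstream decision tree handles missingness natively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import (
    GeneModel,
    RegionClass,
    RegionConfig,
    Transcript,
    classify_region,
    intron_context,
    nearest_splice_distances,
)
from .pwm import PWM, delta_pwm
from .variants import Variant, apply_variant

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class BranchpointConfig:
    """Branchpoint window and AGEZ geometry, nt upstream of the 3'SS."""

    window_min: int = 18
    window_max: int = 44
    agez_bp_margin: int = 15
    min_intron_nt: int = 45

    def __post_init__(self) -> None:
        if not self.window_min < self.window_max:
            raise ValueError("window_min must be < window_max")
        if self.min_intron_nt <= 0:
            raise ValueError("min_intron_nt must be positive")


@dataclass
class FeatureVector:
    """Per-variant feature values with explicit missingness (None)."""

    variant_id: str
    region: RegionClass
    dist_donor: int | None
    dist_acceptor: int | None
    pwm_delta: dict[str, float | None] = field(default_factory=dict)
    ag_created: bool = False
    ag_removed: bool = False
    gt_created: bool = False
    gt_removed: bool = False
    in_agez: bool = False
    agez_skip_prone: bool = False
    bp_distance: int | None = None
    u12: bool | None = None
    min_intron_violation: bool = False
    external: dict[str, float | None] = field(default_factory=dict)
    label: str = "unknown"

    def to_row(self) -> dict[str, object]:
        """Flatten into the model's column registry (NaN for missing)."""
        row: dict[str, object] = {
            "region_donor": float(self.region is RegionClass.DONOR),
            "region_acceptor": float(self.region is RegionClass.ACCEPTOR),
            "region_exon": float(self.region is RegionClass.EXON),
            "region_intron": float(self.region is RegionClass.INTRON),
            "dist_donor": _na(self.dist_donor),
            "dist_acceptor": _na(self.dist_acceptor),
            "ag_created": float(self.ag_created),
            "ag_removed": float(self.ag_removed),
            "gt_created": float(self.gt_created),
            "gt_removed": float(self.gt_removed),
            "in_agez": float(self.in_agez),
            "agez_skip_prone": float(self.agez_skip_prone),
            "bp_distance": _na(self.bp_distance),
            "u12": _na(None if self.u12 is None else float(self.u12)),
            "min_intron_violation": float(self.min_intron_violation),
        }
        for motif, delta in self.pwm_delta.items():
            row[f"pwm_delta_{motif}"] = _na(delta)
        for col, score in self.external.items():
            row[col] = _na(score)
        return row


def _na(v):
    return np.nan if v is None else float(v)


# ---------------------------------------------------------------------------
# dinucleotide creation/removal


def detect_ag_gt_change(
    variant: Variant, ref_context: str, context_start: int
) -> tuple[bool, bool, bool, bool]:
    """Flags for AG/GT dinucleotides created or removed by the variant.

    The affected window is the changed bases plus one flanking base on each
    side; AG and GT occurrences are counted on the ref and alt versions of
    that window and compared (created = more in alt, removed = more in ref,
    independently per dinucleotide).
    """
    lo = max(variant.pos - 1, context_start)
    hi = min(variant.end + 1, context_start + len(ref_context) - 1)
    ref_w = ref_context[lo - context_start : hi - context_start + 1].upper()
    alt_w = apply_variant(ref_w, lo, variant)
    flags = []
    for dinuc in ("AG", "GT"):
        n_ref = _count_overlapping(ref_w, dinuc)
        n_alt = _count_overlapping(alt_w, dinuc)
        flags.extend([n_alt > n_ref, n_ref > n_alt])
    return flags[0], flags[1], flags[2], flags[3]  # ag+, ag-, gt+, gt-


def _count_overlapping(s: str, sub: str) -> int:
    return sum(1 for i in range(len(s) - len(sub) + 1) if s[i : i + len(sub)] == sub)


# ---------------------------------------------------------------------------
# AG exclusion zone


@dataclass(frozen=True)
class AgezResult:
    in_agez: bool
    bp_distance: int | None
    #: "exon_skipping" | "new_splice_site" | None; set only for AG-creating
    #: variants inside the zone
    subcase: str | None = None


def in_ag_exclusion_zone(
    variant: Variant,
    transcript: Transcript,
    strand: str,
    bp_pos: int | None = None,
    cfg: BranchpointConfig = BranchpointConfig(),
    ag_created: bool = False,
) -> AgezResult:
    """AGEZ membership and branchpoint distance for an intronic variant.

    The zone runs from the branchpoint (exclusive) to the acceptor AG
    (exclusive). ``bp_pos`` is the 1-based genomic branchpoint position for
    the containing intron (from an external branchpoint predictor table);
    when absent, the zone start defaults to ``window_max`` nt upstream of
    the 3'SS. Positions at or upstream of the branchpoint are outside the
    zone. For AG-creating variants inside the zone, the subcase splits at
    ``agez_bp_margin`` nt from the branchpoint: closer AGs promote exon
    skipping, more distal ones create a usable cryptic acceptor.
    """
    ctx = intron_context(variant.pos, transcript, strand)
    if ctx is None:
        return AgezResult(False, None)
    (_s, _e), _d5, d3 = ctx  # d3: 1-based nt from the 3'SS (acceptor end)

    # branchpoint distance from the 3'SS, in transcript-sense nt
    if bp_pos is not None:
        bp_ctx = intron_context(bp_pos, transcript, strand)
        if bp_ctx is None:
            raise ValueError("bp_pos is not inside the same intron")
        bp_d3 = bp_ctx[2]
    else:
        bp_d3 = cfg.window_max

    bp_distance = abs(d3 - bp_d3)
    # zone: strictly between branchpoint and the terminal AG (d3 1,2 are the AG)
    in_zone = 2 < d3 < bp_d3
    subcase = None
    if in_zone and ag_created:
        subcase = (
            "exon_skipping" if bp_distance < cfg.agez_bp_margin else "new_splice_site"
        )
    return AgezResult(in_zone, bp_distance, subcase)


# ---------------------------------------------------------------------------
# U12 and minimal intron


def u12_flag(
    variant: Variant,
    transcript: Transcript,
    strand: str,
    u12_intervals: Sequence[tuple[str, int, int]] | None,
) -> bool | None:
    """True iff the variant's containing intron overlaps a U12 interval.

    ``u12_intervals`` are (chrom, start, end) 0-based half-open (BED).
    Returns None (missing) when no U12 annotation was provided, False for
    exonic variants or unlisted introns.
    """
    if u12_intervals is None:
        return None
    ctx = intron_context(variant.pos, transcript, strand)
    if ctx is None:
        return False
    (s, e), _, _ = ctx
    for chrom, us, ue in u12_intervals:
        if chrom == variant.chrom and s < ue and us < e:
            return True
    return False


def min_intron_violation(
    variant: Variant,
    transcript: Transcript,
    cfg: BranchpointConfig = BranchpointConfig(),
) -> bool:
    """True iff an intronic deletion shrinks its intron below the minimum.

    The deleted intronic nt are the overlap of the deleted span with the
    containing intron; the rule fires when remaining length <
    ``cfg.min_intron_nt`` (default 45). Non-deletions are False.
    """
    if variant.vclass not in ("deletion", "insdel"):
        return False
    # deleted reference span, 0-based half-open, excluding the anchor base
    anchored = len(variant.alt) == 1 and variant.ref[:1] == variant.alt
    del_start = variant.pos - 1 + (1 if anchored else 0)
    del_end = variant.pos - 1 + len(variant.ref)
    for s, e in transcript.introns:
        ov = min(e, del_end) - max(s, del_start)
        if ov > 0:
            return (e - s) - ov < cfg.min_intron_nt
    return False


# ---------------------------------------------------------------------------
# assembly


def build_feature_vector(
    variant: Variant,
    gene_models: Sequence[GeneModel],
    genome: Mapping[str, str],
    pwms: Sequence[PWM],
    external_scores: Mapping[str, float | None] | None = None,
    region_cfg: RegionConfig = RegionConfig(),
    bp_cfg: BranchpointConfig = BranchpointConfig(),
    branchpoints: Mapping[tuple[str, int], int] | None = None,
    u12_intervals: Sequence[tuple[str, int, int]] | None = None,
) -> FeatureVector:
    """Assemble the full feature vector for one variant.

    ``genome`` maps chrom -> sequence (e.g. a pyfaidx.Fasta works).
    ``branchpoints`` maps (chrom, 3'SS genomic position 1-based) to the
    branchpoint genomic position. The most splice-proximal transcript
    classification wins when transcripts overlap. Raises when the variant
    lies outside every supplied gene model (such variants should have been
    filtered upstream).
    """
    external_scores = external_scores or {}
    best: tuple[int, RegionClass, Transcript, str] | None = None
    from .genome import _PRECEDENCE  # local to avoid a public re-export

    for gm in gene_models:
        if gm.chrom != variant.chrom:
            continue
        for tx in gm.transcripts:
            rc = (
                RegionClass.EXON
                if gm.structureless and tx.span[0] <= variant.pos - 1 < tx.span[1]
                else classify_region(variant.pos, tx, gm.strand, region_cfg)
            )
            if rc is RegionClass.INTERGENIC:
                continue
            if best is None or _PRECEDENCE[rc] < _PRECEDENCE[best[1]]:
                best = (_PRECEDENCE[rc], rc, tx, gm.strand)
    if best is None:
        raise ValueError(f"variant {variant.key} overlaps no gene model")
    _, region, tx, strand = best

    chrom_seq = str(genome[variant.chrom])
    d_don, d_acc = nearest_splice_distances(variant.pos, tx, strand)

    # dinucleotide flags
    ag_c, ag_r, gt_c, gt_r = detect_ag_gt_change(variant, chrom_seq, 1)

    # ESE/ESS deltas: exonic and near-exonic variants only
    pwm_delta: dict[str, float | None] = {}
    max_width = max((p.width for p in pwms), default=0)
    near_exonic = region in (RegionClass.EXON, RegionClass.DONOR, RegionClass.ACCEPTOR)
    if not near_exonic and d_don is not None and d_acc is not None:
        ctx = intron_context(variant.pos, tx, strand)
        if ctx is not None:
            near_exonic = min(ctx[1], ctx[2]) <= max_width
    for p in pwms:
        if not near_exonic:
            pwm_delta[p.name] = None
            continue
        start = max(1, variant.pos - (p.width - 1))
        end = min(len(chrom_seq), variant.end + (p.width - 1))
        try:
            pwm_delta[p.name] = delta_pwm(
                variant, chrom_seq[start - 1 : end], start, p, strand
            )
        except ValueError:
            pwm_delta[p.name] = None  # context truncated below motif width

    # AGEZ
    bp_pos = None
    ctx = intron_context(variant.pos, tx, strand)
    if ctx is not None and branchpoints is not None:
        (s, e), _, _ = ctx
        three_ss = e if strand == "+" else s + 1  # 1-based last intronic base
        bp_pos = branchpoints.get((variant.chrom, three_ss))
    agez = in_ag_exclusion_zone(variant, tx, strand, bp_pos, bp_cfg, ag_created=ag_c)

    return FeatureVector(
        variant_id=variant.key,
        region=region,
        dist_donor=d_don,
        dist_acceptor=d_acc,
        pwm_delta=pwm_delta,
        ag_created=ag_c,
        ag_removed=ag_r,
        gt_created=gt_c,
        gt_removed=gt_r,
        in_agez=agez.in_agez,
        agez_skip_prone=agez.subcase == "exon_skipping",
        bp_distance=agez.bp_distance,
        u12=u12_flag(variant, tx, strand, u12_intervals),
        min_intron_violation=min_intron_violation(variant, tx, bp_cfg),
        external=dict(external_scores),
    )


def build_feature_matrix(
    variants: Sequence[Variant],
    gene_models: Sequence[GeneModel],
    genome: Mapping[str, str],
    pwms: Sequence[PWM],
    external: Mapping[str, Mapping[str, float | None]] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Feature vectors for many variants as a DataFrame indexed by key.

    ``external`` maps variant key -> {column -> score or None}. Variants
    outside every gene model are dropped (with the same semantics as the
    region filter). A ``region`` string column is included alongside the
    numeric registry columns.
    """
    rows, index, regions = [], [], []
    external = external or {}
    for v in variants:
        fv = build_feature_vector(
            v, gene_models, genome, pwms,
            external_scores=external.get(v.key, {}), **kwargs,
        )
        rows.append(fv.to_row())
        regions.append(str(fv.region))
        index.append(v.key)
    df = pd.DataFrame(rows, index=pd.Index(index, name="key"))
    df.insert(0, "region", regions)
    return df
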