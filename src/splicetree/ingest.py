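"""External splice-predictor score tables: loading, joining, aggregation.

The consensus model consumes scores produced elsewhere by SpliceAI,
MMSplice, Spliceogen, CADD, SPIDEX, dbscSNV and a branchpoint predictor.
Running those tools is out of scope; their outputs are ingested as TSV
tables keyed by the same normalized variant key used by
:mod:`splicetree.variants`, so joins are exact.

Two paper-specific rules live here:

* complex variants (MNV/insdel) are scored by decomposing them into a
  deletion plus an insertion and taking, per score category, the maximum
  over the scored parts;
* when both the SpliceAI-style and the MMSplice-style score groups are
  entirely missing for a variant, the final consensus score is forced to
  zero (those tools' hard-coded region filters otherwise inflate false
  positives on unscored variants).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .variants import Variant, normalize_alleles

#: canonical column schema per supported tool: name -> (columns, (lo, hi) or None)
TOOL_SCHEMAS: dict[str, dict[str, tuple[float, float] | None]] = {
    "spliceai": {
        "ds_ag": (0.0, 1.0),
        "ds_al": (0.0, 1.0),
        "ds_dg": (0.0, 1.0),
        "ds_dl": (0.0, 1.0),
    },
    "mmsplice": {"delta_logit_psi": None},
    "spliceogen": {"donor_gain": (0.0, 1.0), "acceptor_gain": (0.0, 1.0)},
    "cadd": {"phred": (0.0, 99.0)},
    "spidex": {"dpsi_zscore": None},
    "dbscsnv": {"ada": (0.0, 1.0), "rf": (0.0, 1.0)},
    "branchpointer": {"prob": (0.0, 1.0)},
}

#: feature-registry column name for (tool, column)
def feature_column(tool: str, column: str) -> str:
    return f"{tool}_{column}"


#: the two score groups entering the zero rule
ZERO_RULE_GROUPS = ("spliceai", "mmsplice")


@dataclass
class ScoreTable:
    """One external tool's scores, rows keyed by normalized variant key."""

    tool: str
    df: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def columns(self) -> list[str]:
        return list(TOOL_SCHEMAS[self.tool])

    def lookup(self, key: str) -> dict[str, float | None]:
        """Scores for one variant; every column present, None when unscored."""
        if key in self.df.index:
            row = self.df.loc[key]
            return {
                c: (None if pd.isna(row[c]) else float(row[c])) for c in self.columns
            }
        return {c: None for c in self.columns}


def load_score_table(path: str | Path, tool: str) -> ScoreTable:
    """Load one per-tool TSV: chrom, pos, ref, alt plus the tool's columns.

    Keys are re-normalized with the same allele-trimming used for VCF input
    so joins against :func:`splicetree.variants.read_vcf` output are exact.
    Duplicate keys and out-of-range scores are errors.
    """
    if tool not in TOOL_SCHEMAS:
        raise ValueError(f"unknown tool {tool!r}; known: {sorted(TOOL_SCHEMAS)}")
    schema = TOOL_SCHEMAS[tool]
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", *schema}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        return ScoreTable(tool, df.set_index(pd.Index([], name="key"))[list(schema)])

    keys = []
    for i, row in df.iterrows():
        pos, ref, alt = normalize_alleles(int(row["pos"]), str(row["ref"]), str(row["alt"]))
        keys.append(f"{row['chrom']}:{pos}:{ref}:{alt}")
        for col, rng in schema.items():
            val = row[col]
            if pd.isna(val):
                continue
            if rng is not None and not (rng[0] <= float(val) <= rng[1]):
                raise ValueError(
                    f"{path}: row {i} column {col}: {val} outside [{rng[0]}, {rng[1]}]"
                )
    df = df.assign(key=keys)
    dup = df["key"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate keys: {sorted(df.loc[dup, 'key'])[:5]}")
    return ScoreTable(tool, df.set_index("key")[list(schema)])


def gather_external_scores(
    variants: Sequence[Variant],
    tables: Mapping[str, ScoreTable],
    parts: Mapping[str, Sequence[Variant]] | None = None,
) -> dict[str, dict[str, float | None]]:
    """Per-variant external feature columns across all loaded tools.

    ``parts`` maps a complex variant's key to its decomposition parts; for
    those variants each tool category takes the max over scored parts.
    """
    parts = parts or {}
    out: dict[str, dict[str, float | None]] = {}
    for v in variants:
        scores: dict[str, float | None] = {}
        for tool, table in tables.items():
            if v.key in parts:
                per_tool = aggregate_complex_scores(v, parts[v.key], {tool: table})
            else:
                per_tool = table.lookup(v.key)
            for col, val in per_tool.items():
                scores[feature_column(tool, col)] = val
        out[v.key] = scores
    return out


def aggregate_complex_scores(
    v: Variant,
    parts: Sequence[Variant],
    tables: Mapping[str, ScoreTable],
) -> dict[str, float | None]:
    """Max-over-parts aggregation for a decomposed complex variant.

    For each tool score category, the complex variant's score is the
    maximum over the parts that were scored; categories with no scored
    part stay missing. Permutation-invariant and idempotent.
    """
    out: dict[str, float | None] = {}
    for tool, table in tables.items():
        for col in table.columns:
            vals = [
                s for p in parts
                for s in [table.lookup(p.key)[col]]
                if s is not None
            ]
            own = table.lookup(v.key)[col]
            if own is not None:
                vals.append(own)
            out[col] = max(vals) if vals else None
    return out


def apply_zero_rule(
    external: Mapping[str, float | None], model_score: float
) -> float:
    """Force the consensus score to 0 when SpliceAI and MMSplice groups are
    both entirely unscored; otherwise pass ``model_score`` through."""
    if not 0.0 <= model_score <= 1.0 or math.isnan(model_score):
        raise ValueError(f"model_score {model_score} outside [0, 1]")
    for tool in ZERO_RULE_GROUPS:
        for col in TOOL_SCHEMAS[tool]:
            if external.get(feature_column(tool, col)) is not None:
                return model_score
    return 0.0
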