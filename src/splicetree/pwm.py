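"""Position-weight-matrix scoring of exonic splicing enhancer/silencer motifs.

A PWM is a width x 4 table of additive (log-odds-style) per-base weights.
A sequence window of exactly ``width`` nt scores the sum of the weights of
its bases; a longer sequence scores the maximum over all windows. The
variant-level feature is the delta between the best alt-haplotype window
score and the best ref-haplotype window score around the changed bases: a
negative delta on an enhancer motif suggests ESE disruption, a positive
delta on a silencer motif suggests ESS gain.

The packaged matrices cover the SR-protein enhancer motifs SRSF1,
SRSF1 (igM-BRCA2 context), SRSF2, SRSF5 and SRSF6 plus the hnRNP A1
silencer. They are synthetic stand-ins built from the published consensus
motifs (the experimentally derived matrices are not redistributed here);
the files are plain text and fully swappable for user-supplied matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .variants import Variant, apply_variant

_BASES = "ACGT"
_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class PWM:
    name: str
    weights: np.ndarray  # shape (width, 4), columns A C G T
    role: str  # "enhancer" | "silencer"
    score_threshold: float

    def __post_init__(self) -> None:
        if self.weights.ndim != 2 or self.weights.shape[1] != 4:
            raise ValueError("weights must be a (width, 4) array")
        if self.weights.shape[0] < 1:
            raise ValueError("PWM width must be >= 1")
        if self.role not in ("enhancer", "silencer"):
            raise ValueError(f"unknown PWM role {self.role!r}")

    @property
    def width(self) -> int:
        return int(self.weights.shape[0])


def load_pwm(path: str | Path) -> PWM:
    """Parse one PWM file: header ``NAME WIDTH ROLE THRESHOLD`` then
    ``WIDTH`` rows of four tab-separated reals in A C G T order."""
    path = Path(path)
    lines = [
        ln.strip() for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: empty PWM file")
    head = lines[0].split()
    if len(head) != 4:
        raise ValueError(f"{path}: header must be 'NAME WIDTH ROLE THRESHOLD'")
    name, width_s, role, thr_s = head
    width = int(width_s)
    if len(lines) - 1 != width:
        raise ValueError(f"{path}: expected {width} weight rows, got {len(lines) - 1}")
    rows = []
    for ln in lines[1:]:
        vals = ln.split()
        if len(vals) != 4:
            raise ValueError(f"{path}: weight row {ln!r} does not have 4 values")
        rows.append([float(v) for v in vals])
    return PWM(name, np.asarray(rows, dtype=float), role, float(thr_s))


def default_pwms() -> list[PWM]:
    """The six packaged ESE/ESS matrices (synthetic consensus stand-ins)."""
    pkg = resources.files("splicetree") / "data" / "pwm"
    return [load_pwm(p) for p in sorted(pkg.iterdir()) if p.name.endswith(".pwm")]


def score_pwm_window(seq: str, pwm: PWM) -> float:
    """Best (maximum) window score of ``seq`` under ``pwm``.

    Raises for sequences shorter than the motif width. Non-ACGT characters
    make their window score -inf (never the maximum unless unavoidable).
    """
    seq = seq.upper()
    n, w = len(seq), pwm.width
    if n < w:
        raise ValueError(f"sequence length {n} < PWM width {w}")
    idx = np.array([_INDEX.get(b, -1) for b in seq])
    best = -np.inf
    for start in range(n - w + 1):
        window = idx[start : start + w]
        if (window < 0).any():
            score = -np.inf
        else:
            score = float(pwm.weights[np.arange(w), window].sum())
        if score > best:
            best = score
    return best


def delta_pwm(
    variant: Variant,
    ref_context: str,
    context_start: int,
    pwm: PWM,
    strand: str = "+",
) -> float:
    """Change in best motif score caused by a variant.

    ``ref_context`` is reference sequence whose first base sits at 1-based
    ``context_start``; it should span at least ``pwm.width - 1`` nt on each
    side of the changed bases so every overlapping window is seen. The alt
    context is built by applying the variant, and both haplotypes are
    scored over all available windows (minus-strand transcripts score the
    reverse complement). Returns best(alt) - best(ref).
    """
    alt_context = apply_variant(ref_context, context_start, variant)
    ref_seq, alt_seq = ref_context, alt_context
    if strand == "-":
        ref_seq = ref_seq.translate(_COMPLEMENT)[::-1]
        alt_seq = alt_seq.translate(_COMPLEMENT)[::-1]
    return score_pwm_window(alt_seq, pwm) - score_pwm_window(ref_seq, pwm)
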