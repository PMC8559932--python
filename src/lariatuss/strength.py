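"""Splice-site strength scoring with trainable log-odds position weight models.

Windows follow the MaxEntScan convention: a 9-nt donor window (last 3 exonic
+ first 6 intronic bases) and a 23-nt acceptor window (last 20 intronic +
first 3 exonic bases).  The native scorer is a per-position log2-odds PWM
trained from window sequences against a background composition; externally
computed per-sequence score tables (e.g. real MaxEntScan output) can be
loaded in its place through ``read_score_table``.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .annotation import ACCEPTOR, DONOR
from .stats import bh_fdr

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: (exonic nt, intronic nt) of the scoring window, per site kind.
WINDOW_SPLIT = {DONOR: (3, 6), ACCEPTOR: (3, 20)}
WINDOW_LENGTH = {DONOR: 9, ACCEPTOR: 23}


@dataclass
class PositionWeightModel:
    """Per-position log2-odds weights over {A, C, G, T} vs a background.

    ``weights[i, j]`` is log2(freq of base j at position i / background of
    base j); frequencies carry the training pseudocount so weights are
    always finite.
    """

    kind: str
    weights: np.ndarray  # (window, 4)
    frequencies: np.ndarray  # (window, 4)
    background: np.ndarray  # (4,)
    pseudocount: float
    n_train: int
    window: int = field(init=False)

    def __post_init__(self):
        self.window = self.weights.shape[0]
        if self.kind not in WINDOW_LENGTH:
            raise ValueError(f"invalid model kind {self.kind!r}")
        if self.window != WINDOW_LENGTH[self.kind]:
            raise ValueError(
                f"{self.kind} model must have window {WINDOW_LENGTH[self.kind]}, got {self.window}"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite weights (train with pseudocount > 0)")

    def consensus(self) -> str:
        return "".join(BASES[j] for j in self.weights.argmax(axis=1))

    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())


def train_model(
    sequences: Iterable[str],
    kind: str,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.5,
) -> PositionWeightModel:
    """Estimate a PWM from window sequences of one kind.

    N bases are excluded from the per-position counts.  The background
    defaults to the training set's overall base composition (pseudocounted);
    with a uniform training set and uniform background all weights are 0.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    seqs = [s.upper() for s in sequences]
    if not seqs:
        raise ValueError("empty training set")
    w = WINDOW_LENGTH[kind] if kind in WINDOW_LENGTH else None
    if w is None:
        raise ValueError(f"invalid kind {kind!r}")
    bad = [s for s in seqs if len(s) != w]
    if bad:
        raise ValueError(f"{len(bad)} training sequence(s) not of length {w}: {bad[:5]}")
    counts = np.zeros((w, 4))
    for s in seqs:
        for i, ch in enumerate(s):
            j = _BASE_INDEX.get(ch)
            if j is not None:
                counts[i, j] += 1
    freqs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
    if background is None:
        total = counts.sum(axis=0) + pseudocount
        bg = total / total.sum()
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 frequencies summing to 1")
    weights = np.log2(freqs / bg)
    return PositionWeightModel(kind, weights, freqs, bg, pseudocount, len(seqs))


def score_sequence(model: PositionWeightModel, sequence: str) -> tuple[float, bool]:
    """Sum of per-position weights, in bits; higher = stronger site.

    Non-ACGT positions contribute 0 and set the returned flag.
    """
    s = sequence.upper()
    if len(s) != model.window:
        raise ValueError(f"sequence length {len(s)} != model window {model.window}")
    score = 0.0
    flagged = False
    for i, ch in enumerate(s):
        j = _BASE_INDEX.get(ch)
        if j is None:
            flagged = True
        else:
            score += model.weights[i, j]
    return float(score), flagged


def score_many(model: PositionWeightModel, sequences: Sequence[str]) -> np.ndarray:
    return np.array([score_sequence(model, s)[0] for s in sequences])


def sample_windows(model_freqs: np.ndarray, n: int, rng: np.random.Generator) -> list[str]:
    """Draw window strings from per-position base frequencies (generator aid)."""
    w = model_freqs.shape[0]
    out = []
    for _ in range(n):
        idx = [rng.choice(4, p=model_freqs[i]) for i in range(w)]
        out.append("".join(BASES[j] for j in idx))
    return out


def write_model(model: PositionWeightModel, path) -> None:
    """TSV with '#'-prefixed metadata lines, then one row per position."""
    lines = [
        f"# kind\t{model.kind}",
        f"# window\t{model.window}",
        f"# pseudocount\t{model.pseudocount!r}",
        f"# n_train\t{model.n_train}",
        "# background\t" + "\t".join(repr(float(x)) for x in model.background),
        "position\t" + "\t".join(BASES) + "\t" + "\t".join(f"freq_{b}" for b in BASES),
    ]
    for i in range(model.window):
        row = [str(i)]
        row += [repr(float(x)) for x in model.weights[i]]
        row += [repr(float(x)) for x in model.frequencies[i]]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_model(path) -> PositionWeightModel:
    meta: dict[str, list[str]] = {}
    rows = []
    header_seen = False
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            meta[parts[0].strip()] = parts[1:]
        elif not header_seen:
            header_seen = True
        elif line.strip():
            rows.append(line.split("\t"))
    window = int(meta["window"][0])
    weights = np.array([[float(r[1 + j]) for j in range(4)] for r in rows])
    freqs = np.array([[float(r[5 + j]) for j in range(4)] for r in rows])
    if weights.shape[0] != window:
        raise ValueError(f"model file {path}: {weights.shape[0]} rows, window {window}")
    return PositionWeightModel(
        meta["kind"][0],
        weights,
        freqs,
        np.array([float(x) for x in meta["background"]]),
        float(meta["pseudocount"][0]),
        int(meta["n_train"][0]),
    )


def write_score_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_score_table(path) -> pd.DataFrame:
    """Load a per-sequence score table (site_id, score[, group]) — the entry
    point for externally computed scores such as real MaxEntScan output."""
    df = pd.read_csv(path, sep="\t")
    if "site_id" not in df.columns or "score" not in df.columns:
        raise ValueError(f"{path}: expected columns site_id and score")
    return df


GROUP_DECREASED = "usage-decreased"
GROUP_INCREASED = "usage-increased"
GROUP_UNCHANGED = "unchanged"


def groups_from_uss(uss_table: pd.DataFrame, delta_threshold: float = 0.01) -> pd.Series:
    """Map each screened site to a strength-comparison group.

    Significant sites split by delta sign; sites with |dUSS| below the
    threshold form the unchanged reference group; the rest (large but
    non-significant shifts) are left out (NaN).
    """
    sig = uss_table["significant"]
    delta = uss_table["delta_uss"]
    group = pd.Series(np.nan, index=uss_table.index, dtype=object)
    group[sig & (delta < 0)] = GROUP_DECREASED
    group[sig & (delta > 0)] = GROUP_INCREASED
    group[~sig & (delta.abs() < delta_threshold)] = GROUP_UNCHANGED
    return group


def summarize_by_group(scores: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean/median/SE plus pairwise two-sided rank-sum tests.

    ``scores`` needs columns ``score`` and ``group``.  Groups with fewer
    than two members get SE = NaN; pairwise Mann-Whitney U p-values are
    BH-corrected.  With a single group the pairwise table is empty.
    """
    df = scores.dropna(subset=["group"])
    rows = []
    for g, grp in df.groupby("group", sort=True):
        v = grp["score"].to_numpy(dtype=float)
        se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size >= 2 else np.nan
        rows.append((g, v.size, float(v.mean()), float(np.median(v)), se))
    summary = pd.DataFrame(rows, columns=["group", "n", "mean", "median", "se"])
    pair_rows = []
    groups = list(summary["group"])
    for g1, g2 in combinations(groups, 2):
        v1 = df.loc[df["group"] == g1, "score"]
        v2 = df.loc[df["group"] == g2, "score"]
        if len(v1) and len(v2):
            p = float(mannwhitneyu(v1, v2, alternative="two-sided").pvalue)
        else:
            p = np.nan
        pair_rows.append((g1, g2, len(v1), len(v2), p))
    pairs = pd.DataFrame(pair_rows, columns=["group_1", "group_2", "n_1", "n_2", "p_value"])
    pairs["fdr"] = bh_fdr(pairs["p_value"]) if len(pairs) else pd.Series(dtype=float)
    return summary, pairs
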