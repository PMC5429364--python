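"""Sequence-consensus analyses of protean and disordered residues.

Three analyses that probe what distinguishes protean segments (disordered
regions that fold on binding) from the rest of the sequence space:

* amino-acid propensity: how over/under-represented each amino acid is in a
  residue class relative to the full corpus,
  Pr(X) = (N(X)_class / N(All)_class) / (N(X)_full / N(All)_full);
* secondary-structure content: the H/E/C fractions of the predicted
  secondary structure within a residue class;
* Altscore: transitions-per-residue of the predicted secondary-structure
  string over a segment, a measure of how "indecisive" a segment is about
  adopting any single secondary structure.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._aa_tables import AA_ORDER


@dataclass
class PropensityTable:
    class_label: str
    propensities: dict[str, float]
    class_counts: dict[str, int]
    full_counts: dict[str, int]

    def __getitem__(self, aa: str) -> float:
        return self.propensities[aa]


def count_residues(sequence: str, mask: np.ndarray | None = None) -> Counter:
    """Per-amino-acid counts, restricted to a boolean residue mask if given."""
    if mask is None:
        sel = sequence
    else:
        mask = np.asarray(mask).astype(bool)
        if mask.shape[0] != len(sequence):
            raise ValueError("mask length does not match sequence")
        sel = "".join(aa for aa, m in zip(sequence, mask) if m)
    return Counter(aa for aa in sel if aa in AA_ORDER)


def propensity(
    class_counts: dict[str, int],
    full_counts: dict[str, int],
    class_label: str = "",
    denominator: str = "corrected",
) -> PropensityTable:
    """Per-amino-acid propensity of a residue class against the full corpus.

    ``denominator="corrected"`` normalises the class frequency by the class
    total, giving the ratio of two proper frequencies (a class that covers
    almost the whole corpus then has all propensities ~1). The alternative
    ``"printed"`` form divides the class count by the *full* total instead.
    """
    full_total = sum(full_counts.get(aa, 0) for aa in AA_ORDER)
    class_total = sum(class_counts.get(aa, 0) for aa in AA_ORDER)
    if full_total == 0:
        raise ValueError("empty full-corpus counts")
    if class_total == 0:
        raise ValueError(f"empty class counts for {class_label!r}")
    props: dict[str, float] = {}
    for aa in AA_ORDER:
        n_full = full_counts.get(aa, 0)
        if n_full == 0:
            warnings.warn(f"amino acid {aa} absent from the full corpus; excluded")
            continue
        n_class = class_counts.get(aa, 0)
        class_freq = n_class / (class_total if denominator == "corrected" else full_total)
        props[aa] = class_freq / (n_full / full_total)
    return PropensityTable(
        class_label=class_label,
        propensities=props,
        class_counts={aa: class_counts.get(aa, 0) for aa in AA_ORDER},
        full_counts={aa: full_counts.get(aa, 0) for aa in AA_ORDER},
    )


def ss_content(ss_calls: str, mask: np.ndarray | None = None) -> dict[str, float]:
    """H/E/C fractions of the secondary-structure calls under a residue mask."""
    if mask is None:
        mask = np.ones(len(ss_calls), dtype=bool)
    mask = np.asarray(mask).astype(bool)
    if mask.shape[0] != len(ss_calls):
        raise ValueError("mask length does not match calls")
    sel = [c for c, m in zip(ss_calls, mask) if m]
    if not sel:
        raise ValueError("mask selects no residues")
    n = len(sel)
    counts = Counter(sel)
    return {k: counts.get(k, 0) / n for k in "HEC"}


def pooled_ss_content(
    calls_and_masks: Iterable[tuple[str, np.ndarray]]
) -> dict[str, float]:
    """H/E/C fractions pooled over many (calls, mask) pairs."""
    counts: Counter = Counter()
    total = 0
    for calls, mask in calls_and_masks:
        mask = np.asarray(mask).astype(bool)
        sel = [c for c, m in zip(calls, mask) if m]
        counts.update(sel)
        total += len(sel)
    if total == 0:
        raise ValueError("no residues selected")
    return {k: counts.get(k, 0) / total for k in "HEC"}


def altscore(ss_calls_segment: str, denominator: str = "length") -> float:
    """Transitions-per-residue of a secondary-structure string.

    A transition is any adjacent pair of unequal calls (H->C, C->E, ...).
    ``denominator="length"`` divides by the segment length (default);
    ``"length-1"`` divides by the number of adjacent pairs.
    """
    n = len(ss_calls_segment)
    if n < 1:
        raise ValueError("empty segment")
    transitions = sum(
        1 for a, b in zip(ss_calls_segment, ss_calls_segment[1:]) if a != b
    )
    if denominator == "length":
        return transitions / n
    if n == 1:
        return 0.0
    return transitions / (n - 1)


@dataclass
class AltscoreResult:
    segment_id: str
    class_label: str  # "protean" | "non_protean" | ...
    length: int
    transitions: int
    altscore: float
    calls: str


def segment_altscores(
    segments: Iterable[tuple[str, str, str]], denominator: str = "length"
) -> list[AltscoreResult]:
    """Altscore for each (segment_id, class_label, ss_calls) triple."""
    out = []
    for seg_id, label, calls in segments:
        score = altscore(calls, denominator)
        transitions = sum(1 for a, b in zip(calls, calls[1:]) if a != b)
        out.append(
            AltscoreResult(
                segment_id=seg_id,
                class_label=label,
                length=len(calls),
                transitions=transitions,
                altscore=score,
                calls=calls,
            )
        )
    return out


def altscore_distribution(
    segments: Sequence[AltscoreResult],
    exclude_zero: bool = True,
    exclude_pure_coil: bool = True,
    bin_width: float = 0.025,
) -> dict[str, dict]:
    """Normalised Altscore histograms per class, on a fixed [0, 1] bin grid.

    Zero-Altscore segments and pure-coil segments carry no signal about
    secondary-structure indecisiveness and are excluded by default. Reports
    each class's histogram, surviving-segment count, and peak (modal bin
    centre).
    """
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2
    out: dict[str, dict] = {}
    for label in sorted({s.class_label for s in segments}):
        vals = []
        for s in segments:
            if s.class_label != label:
                continue
            if exclude_zero and s.altscore == 0.0:
                continue
            if exclude_pure_coil and set(s.calls) == {"C"}:
                continue
            vals.append(s.altscore)
        if not vals:
            raise ValueError(f"all segments of class {label!r} were filtered out")
        hist, _ = np.histogram(vals, bins=edges)
        density = hist / hist.sum()
        out[label] = {
            "bin_centers": centers,
            "density": density,
            "n_segments": len(vals),
            "peak": float(centers[int(np.argmax(density))]),
            "mean": float(np.mean(vals)),
        }
    return out
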