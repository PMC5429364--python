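"""Sliding-window sequence features and full feature-matrix assembly.

Every residue is described by 342 features in seven groups, computed over a
15-residue window centred on the residue (window size configurable, odd,
9-21):

1. mutability (1-300): the 20 min-max-scaled PSSM log-odds for each of the
   15 window positions, zero-padded past the termini;
2. conservation (301): window mean of the PSSM per-position information;
3. composition (302-321): fraction of each amino acid in the window;
4. physicochemical properties (322-330): polarity-class fractions (4),
   charge-class fractions (3), mean Kyte-Doolittle hydropathy, mean residue
   mass;
5. predicted secondary structure (331-333): window means of P(H), P(E), P(C);
6. predicted disorder (334-340) and 7. disorder topography (341-342):
   delegated to :mod:`proteus.disorder_features`.

Averaged features (groups 2-5) use truncated windows at the termini: the
divisor is the number of in-sequence positions, so terminal residues are not
biased toward zero. Group 1 keeps fixed dimensionality by zero-padding.
Ambiguity codes (X/B/Z/U...) contribute zero counts and are excluded from
composition/property divisors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._aa_tables import (
    AA_ORDER,
    CHARGE_MATRIX,
    KD_VECTOR,
    MASS_VECTOR,
    POLARITY_MATRIX,
    encode_sequence,
)
from .disorder_features import (
    DEFAULT_CONFIG,
    DisorderConfig,
    disorder_segment_matrix,
    topography_matrix,
)
from .io_tracks import (
    DisorderProfile,
    FormatError,
    PSSMProfile,
    SecondaryStructureProfile,
)

N_FEATURES = 342

#: 1-based inclusive column ranges per feature group.
GROUP_RANGES: dict[int, tuple[int, int]] = {
    1: (1, 300),
    2: (301, 301),
    3: (302, 321),
    4: (322, 330),
    5: (331, 333),
    6: (334, 340),
    7: (341, 342),
}

GROUP_NAMES = {
    1: "amino acid mutability",
    2: "amino acid conservation",
    3: "amino acid concentration",
    4: "amino acid properties",
    5: "predicted secondary structure",
    6: "predicted disorder",
    7: "disorder topography",
}


def group_columns(groups: set[int] | frozenset[int] | None = None) -> np.ndarray:
    """0-based column indices covered by the given feature groups (default all)."""
    groups = set(GROUP_RANGES) if groups is None else set(groups)
    bad = groups - set(GROUP_RANGES)
    if bad:
        raise ValueError(f"unknown feature groups {sorted(bad)}")
    cols: list[int] = []
    for g in sorted(groups):
        lo, hi = GROUP_RANGES[g]
        cols.extend(range(lo - 1, hi))
    return np.asarray(cols, dtype=np.int64)


def feature_names() -> list[str]:
    """Stable names for all 342 columns, window offsets included for group 1."""
    names: list[str] = []
    for off in range(-7, 8):
        names += [f"pssm[{off:+d}]:{aa}" for aa in AA_ORDER]
    names.append("conservation")
    names += [f"comp:{aa}" for aa in AA_ORDER]
    names += [f"polarity:{c}" for c in ("nonpolar", "polar", "acidic", "basic")]
    names += [f"charge:{c}" for c in ("positive", "negative", "neutral")]
    names += ["hydropathy", "mass"]
    names += ["ss:H", "ss:E", "ss:C"]
    names += [
        "diso:window_mean",
        "diso:dis_len", "diso:dis_start", "diso:dis_stop",
        "diso:ord_len", "diso:ord_start", "diso:ord_stop",
    ]
    names += ["topo:class", "topo:run_length"]
    assert len(names) == N_FEATURES
    return names


@dataclass(frozen=True)
class FeatureConfig:
    window_size: int = 15
    disorder: DisorderConfig = field(default_factory=DisorderConfig)

    def __post_init__(self) -> None:
        w = self.window_size
        if w % 2 == 0 or not 9 <= w <= 21:
            raise ValueError(f"window_size must be odd and in [9, 21], got {w}")


@dataclass
class PssmScaler:
    """Per-amino-acid min/max fitted on a training corpus.

    Transform maps each PSSM cell to (v - min)/(max - min) for its
    amino-acid column, clamped to [0, 1]; a degenerate column (min == max)
    maps to the uninformative midpoint 0.5.
    """

    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, profiles: list[PSSMProfile]) -> "PssmScaler":
        if not profiles:
            raise ValueError("cannot fit a PSSM scaler on an empty corpus")
        stacked = np.vstack([p.scores for p in profiles])
        return cls(stacked.min(axis=0), stacked.max(axis=0))

    def transform(self, profile: PSSMProfile) -> PSSMProfile:
        span = self.maxs - self.mins
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = (profile.scores - self.mins) / span
        scaled = np.where(span == 0, 0.5, scaled)
        return PSSMProfile(
            np.clip(scaled, 0.0, 1.0), profile.info, protein_id=profile.protein_id
        )


def fit_pssm_scaler(profiles: list[PSSMProfile]) -> PssmScaler:
    return PssmScaler.fit(profiles)


def scale_pssm(profile: PSSMProfile, scaler: PssmScaler) -> PSSMProfile:
    return scaler.transform(profile)


# ---------------------------------------------------------------------------
# Windowed primitives. All return the full L x k block; the per-residue
# functions of the public API index into them.


def _window_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Truncated-window mean along axis 0 (divisor = in-sequence positions)."""
    v = np.atleast_2d(values.T).T.astype(float)
    L = v.shape[0]
    half = window // 2
    csum = np.vstack([np.zeros((1, v.shape[1])), np.cumsum(v, axis=0)])
    idx = np.arange(L)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, L - 1)
    out = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)[:, None]
    return out if values.ndim > 1 else out[:, 0]


def _window_ratio(num: np.ndarray, den: np.ndarray, window: int) -> np.ndarray:
    """Windowed sum of num divided by windowed sum of den (0 when den sums to 0)."""
    n = np.atleast_2d(num.T).T.astype(float)
    L = n.shape[0]
    half = window // 2
    csn = np.vstack([np.zeros((1, n.shape[1])), np.cumsum(n, axis=0)])
    csd = np.concatenate([[0.0], np.cumsum(den.astype(float))])
    idx = np.arange(L)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, L - 1)
    nsum = csn[hi + 1] - csn[lo]
    dsum = csd[hi + 1] - csd[lo]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = nsum / dsum[:, None]
    out[dsum == 0] = 0.0
    return out


def mutability_matrix(scaled: PSSMProfile, window: int = 15) -> np.ndarray:
    """L x (20*window) group-1 block: scaled PSSM rows at offsets -h..+h, zero-padded."""
    half = window // 2
    L = len(scaled)
    padded = np.zeros((L + 2 * half, 20))
    padded[half : half + L] = scaled.scores
    blocks = [padded[off : off + L] for off in range(window)]
    return np.hstack(blocks)


def mutability_features(scaled: PSSMProfile, pos: int, window: int = 15) -> np.ndarray:
    """Group-1 vector (20*window values) for one residue, 1-based pos."""
    if not 1 <= pos <= len(scaled):
        raise IndexError(f"position {pos} outside [1, {len(scaled)}]")
    return mutability_matrix(scaled, window)[pos - 1]


def conservation_track(profile: PSSMProfile, window: int = 15) -> np.ndarray:
    return _window_mean(profile.info, window)


def conservation_feature(profile: PSSMProfile, pos: int, window: int = 15) -> float:
    return float(conservation_track(profile, window)[pos - 1])


def composition_matrix(sequence: str, window: int = 15) -> np.ndarray:
    """L x 20 group-3 block: amino-acid fractions over the window.

    Divisor is the count of in-window standard residues, so ambiguity codes
    neither count toward any amino acid nor dilute the fractions.
    """
    codes = encode_sequence(sequence)
    onehot = np.zeros((len(sequence), 20))
    std = codes >= 0
    onehot[np.flatnonzero(std), codes[std]] = 1.0
    return _window_ratio(onehot, std, window)


def composition_features(sequence: str, pos: int, window: int = 15) -> np.ndarray:
    return composition_matrix(sequence, window)[pos - 1]


def property_matrix(sequence: str, window: int = 15) -> np.ndarray:
    """L x 9 group-4 block: polarity fractions (4), charge fractions (3),
    mean hydropathy, mean residue mass."""
    codes = encode_sequence(sequence)
    std = codes >= 0
    L = len(sequence)
    onehot = np.zeros((L, 20))
    onehot[np.flatnonzero(std), codes[std]] = 1.0
    polarity = _window_ratio(onehot @ POLARITY_MATRIX.T, std, window)
    charge = _window_ratio(onehot @ CHARGE_MATRIX.T, std, window)
    kd = _window_ratio(onehot @ KD_VECTOR, std, window)
    mass = _window_ratio(onehot @ MASS_VECTOR, std, window)
    return np.hstack([polarity, charge, kd, mass])


def property_features(sequence: str, pos: int, window: int = 15) -> np.ndarray:
    return property_matrix(sequence, window)[pos - 1]


def ss_matrix(ss: SecondaryStructureProfile, window: int = 15) -> np.ndarray:
    """L x 3 group-5 block: window means of P(H), P(E), P(C)."""
    return _window_mean(ss.probs, window)


def ss_features(ss: SecondaryStructureProfile, pos: int, window: int = 15) -> np.ndarray:
    return ss_matrix(ss, window)[pos - 1]


# ---------------------------------------------------------------------------
# Assembly


@dataclass
class FeatureMatrix:
    """L x 342 per-residue feature matrix with the group -> column map."""

    values: np.ndarray
    protein_id: str = ""
    group_index: dict[int, tuple[int, int]] = field(
        default_factory=lambda: dict(GROUP_RANGES)
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(
                f"feature matrix must have {N_FEATURES} columns, "
                f"got {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")

    def __len__(self) -> int:
        return self.values.shape[0]

    def columns(self, groups: set[int] | None = None) -> np.ndarray:
        return self.values[:, group_columns(groups)]


def assemble_features(
    sequence: str,
    scaled_pssm: PSSMProfile,
    ss: SecondaryStructureProfile,
    diso: DisorderProfile,
    config: FeatureConfig | None = None,
    protein_id: str = "",
) -> FeatureMatrix:
    """Assemble the full L x 342 matrix, column-ordered by feature group."""
    cfg = config or FeatureConfig()
    L = len(sequence)
    for name, track in (("pssm", scaled_pssm), ("ss2", ss), ("diso", diso)):
        if len(track) != L:
            raise FormatError(
                f"{name} track length {len(track)} != sequence length {L}"
            )
    w = cfg.window_size
    # Group 1 is the only group whose natural width tracks the window size.
    # The assembled matrix keeps the fixed 342-column layout: for windows
    # narrower than 15 the absent outer offsets are zero columns, aligned so
    # that column block k always means window offset k-7.
    g1w = min(w, 15)
    g1 = mutability_matrix(scaled_pssm, g1w)
    if g1w < 15:
        side = np.zeros((L, 10 * (15 - g1w)))
        g1 = np.hstack([side, g1, side])
    blocks = [
        g1,
        conservation_track(scaled_pssm, w)[:, None],
        composition_matrix(sequence, w),
        property_matrix(sequence, w),
        ss_matrix(ss, w),
        disorder_segment_matrix(diso, window=w, config=cfg.disorder),
        topography_matrix(diso, cfg.disorder),
    ]
    return FeatureMatrix(np.hstack(blocks), protein_id=protein_id)
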