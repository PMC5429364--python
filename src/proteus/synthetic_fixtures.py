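"""Self-contained synthetic corpora for the full pipeline.

Real inputs to this predictor are produced by heavyweight external tools
(iterative homology search for PSSMs, secondary-structure and disorder
predictors) over curated databases. The generator emulates the *statistical
structure* of those inputs so every stage is testable offline:

* ordered regions drawn from a globular background composition; disordered
  regions enriched in disorder-promoting residues (P, G, S, D, E, K, R) and
  depleted in large hydrophobics and cysteine;
* protean sub-segments (placed only inside disordered regions, length mode
  near 15 residues) re-enriched in large hydrophobics (L, I, F, Y, W) and
  charged residues (D, E, K, R), depleted in P, G, C — the signature of
  segments that fold on binding;
* a disorder track that plateaus high over disordered regions and low over
  ordered ones, with a local valley dipping (but staying >= 0.5) over each
  protean segment, plus bounded noise;
* three-state secondary structure from a switching process that is
  coil-dominant in disordered regions and switches states more often inside
  protean segments (higher "indecisiveness");
* pseudo-PSSM rows peaked on the true residue with integer noise, and a
  per-position information track that is lower in disordered regions;
* optional mutated duplicates of earlier proteins, giving non-trivial
  sequence families for cluster-grouped cross-validation.

What the generator does NOT emulate: realistic homology-profile score
distributions, correlated errors between tracks, or real protean biology —
passing parameter-recovery tests shows the pipeline's arithmetic is right,
not that the predictor works on real proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from ._aa_tables import AA_ORDER, PSIBLAST_ORDER
from .io_tracks import (
    ClusterAssignment,
    DisorderProfile,
    PSSMProfile,
    ProteanLabels,
    ProteinData,
    SecondaryStructureProfile,
    SequenceRecord,
    write_segment_labels,
)

# Background (globular/ordered) amino-acid frequencies, alphabetical order.
_ORDERED_FREQ = {
    "A": 8.3, "C": 1.7, "D": 5.3, "E": 6.2, "F": 4.1, "G": 7.2, "H": 2.2,
    "I": 5.9, "K": 5.8, "L": 9.7, "M": 2.4, "N": 4.3, "P": 4.7, "Q": 3.9,
    "R": 5.1, "S": 6.5, "T": 5.4, "V": 6.9, "W": 1.1, "Y": 3.2,
}

# Multiplicative composition biases relative to the ordered background.
_DISORDER_BIAS = {
    "P": 1.9, "G": 1.6, "S": 1.7, "D": 1.5, "E": 1.6, "K": 1.5, "R": 1.3,
    "Q": 1.2, "W": 0.3, "F": 0.35, "Y": 0.35, "I": 0.4, "L": 0.4,
    "V": 0.55, "M": 0.55, "C": 0.25,
}
# Applied on top of the disordered composition inside protean segments.
_PROTEAN_BIAS = {
    "L": 4.5, "I": 5.0, "F": 5.0, "Y": 6.0, "W": 10.0,
    "D": 1.6, "E": 1.6, "K": 1.6, "R": 1.7,
    "P": 0.4, "G": 0.45, "S": 0.6, "C": 0.35,
}


def _composition(base: dict[str, float], bias: dict[str, float] | None = None) -> np.ndarray:
    freq = np.array([base[aa] for aa in AA_ORDER])
    if bias:
        freq = freq * np.array([bias.get(aa, 1.0) for aa in AA_ORDER])
    return freq / freq.sum()


ORDERED_COMPOSITION = _composition(_ORDERED_FREQ)
DISORDERED_COMPOSITION = _composition(_ORDERED_FREQ, _DISORDER_BIAS)
PROTEAN_COMPOSITION = _composition(
    {aa: f for aa, f in zip(AA_ORDER, DISORDERED_COMPOSITION)}, _PROTEAN_BIAS
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults target the corpus statistics this predictor was designed for:
    ~2% protean residues overall, protean segment lengths with a mode near
    15 residues (range 5-60), coil-dominant disordered regions, and a
    disorder track whose valleys coincide with protean segments.
    """

    n_proteins: int = 200
    length_range: tuple[int, int] = (100, 300)
    disordered_fraction: float = 0.40
    protean_protein_fraction: float = 0.25
    protean_length_mu: float = 2.868  # ln-scale; mode ~15 with sigma 0.4
    protean_length_sigma: float = 0.4
    protean_length_bounds: tuple[int, int] = (5, 60)
    # disorder track
    disorder_base_ordered: float = 0.20
    disorder_base_disordered: float = 0.80
    valley_depth: float = 0.25
    disorder_noise: float = 0.05
    # secondary-structure switching process: target state distributions
    # (H, E, C) and per-residue switch probabilities
    ss_dist_ordered: tuple[float, float, float] = (0.35, 0.20, 0.45)
    ss_dist_disordered: tuple[float, float, float] = (0.10, 0.05, 0.85)
    ss_dist_protean: tuple[float, float, float] = (0.32, 0.08, 0.60)
    ss_switch_ordered: float = 0.10
    ss_switch_disordered: float = 0.08
    ss_switch_protean: float = 0.25
    # pseudo-PSSM
    pssm_match_score: float = 5.0
    pssm_mismatch_score: float = -2.0
    pssm_noise: float = 1.5
    info_ordered: float = 1.4
    info_disordered: float = 0.55
    info_noise: float = 0.2
    # sequence families
    duplicate_fraction: float = 0.15
    mutation_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("disordered_fraction", "protean_protein_fraction",
                     "disorder_noise", "duplicate_fraction", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class RegionMap:
    """Ground-truth region structure of one synthetic protein (1-based, inclusive)."""

    disordered: list[tuple[int, int]]
    protean: list[tuple[int, int]]

    def disordered_mask(self, length: int) -> np.ndarray:
        m = np.zeros(length, dtype=bool)
        for s, e in self.disordered:
            m[s - 1 : e] = True
        return m

    def protean_mask(self, length: int) -> np.ndarray:
        m = np.zeros(length, dtype=bool)
        for s, e in self.protean:
            m[s - 1 : e] = True
        return m


@dataclass
class SyntheticCorpus:
    proteins: list[ProteinData]
    region_maps: dict[str, RegionMap]
    clusters: ClusterAssignment
    config: GeneratorConfig

    def __iter__(self):
        return iter(self.proteins)

    def __len__(self) -> int:
        return len(self.proteins)

    def labels(self) -> dict[str, np.ndarray]:
        return {p.id: p.labels.labels for p in self.proteins}


# ---------------------------------------------------------------------------
# Track builders


def _draw_regions(rng: np.random.Generator, L: int, config: GeneratorConfig) -> RegionMap:
    dis_total = int(round(config.disordered_fraction * L))
    regions: list[tuple[int, int]] = []
    if dis_total >= 5:
        n_regions = 1 if dis_total < 40 or rng.random() < 0.7 else 2
        budgets = [dis_total] if n_regions == 1 else [dis_total // 2, dis_total - dis_total // 2]
        # place regions in disjoint halves of the sequence
        bounds = [(1, L)] if n_regions == 1 else [(1, L // 2), (L // 2 + 1, L)]
        for budget, (lo, hi) in zip(budgets, bounds):
            budget = min(budget, hi - lo + 1)
            if budget < 5:
                continue
            start = int(rng.integers(lo, hi - budget + 2))
            regions.append((start, start + budget - 1))
    protean: list[tuple[int, int]] = []
    if regions and rng.random() < config.protean_protein_fraction:
        host = regions[int(rng.integers(len(regions)))]
        host_len = host[1] - host[0] + 1
        lo_b, hi_b = config.protean_length_bounds
        if host_len >= lo_b:
            raw = rng.lognormal(config.protean_length_mu, config.protean_length_sigma)
            seg_len = int(np.clip(round(raw), lo_b, min(hi_b, host_len)))
            start = int(rng.integers(host[0], host[1] - seg_len + 2))
            protean.append((start, start + seg_len - 1))
    return RegionMap(disordered=regions, protean=protean)


def _draw_sequence(rng: np.random.Generator, L: int, regions: RegionMap) -> str:
    codes = rng.choice(20, size=L, p=ORDERED_COMPOSITION)
    dis = regions.disordered_mask(L)
    n_dis = int(dis.sum())
    if n_dis:
        codes[dis] = rng.choice(20, size=n_dis, p=DISORDERED_COMPOSITION)
    pro = regions.protean_mask(L)
    n_pro = int(pro.sum())
    if n_pro:
        codes[pro] = rng.choice(20, size=n_pro, p=PROTEAN_COMPOSITION)
    return "".join(AA_ORDER[c] for c in codes)


def _disorder_track(
    rng: np.random.Generator, L: int, regions: RegionMap, config: GeneratorConfig
) -> np.ndarray:
    track = np.full(L, config.disorder_base_ordered)
    track[regions.disordered_mask(L)] = config.disorder_base_disordered
    for s, e in regions.protean:
        # cosine-profile valley, deepest at the segment centre
        idx = np.arange(s - 1, e)
        width = e - s + 1
        profile = 0.5 * (1 - np.cos(2 * np.pi * (idx - (s - 1) + 0.5) / width))
        track[idx] -= config.valley_depth * profile
    if config.disorder_noise > 0:
        track += rng.uniform(-config.disorder_noise, config.disorder_noise, size=L)
    return np.round(np.clip(track, 0.0, 1.0), 3)


def _ss_track(
    rng: np.random.Generator, L: int, regions: RegionMap, config: GeneratorConfig
) -> tuple[np.ndarray, str]:
    dis = regions.disordered_mask(L)
    pro = regions.protean_mask(L)
    dists = np.array(
        [config.ss_dist_ordered, config.ss_dist_disordered, config.ss_dist_protean]
    )
    switch = np.array(
        [config.ss_switch_ordered, config.ss_switch_disordered, config.ss_switch_protean]
    )
    regime = np.zeros(L, dtype=int)
    regime[dis] = 1
    regime[pro] = 2
    states = np.empty(L, dtype=int)
    states[0] = rng.choice(3, p=dists[regime[0]] / dists[regime[0]].sum())
    for i in range(1, L):
        r = regime[i]
        # redraw at regime boundaries so each region sits at its target
        # state distribution instead of inheriting the neighbour's state
        if r != regime[i - 1] or rng.random() < switch[r]:
            states[i] = rng.choice(3, p=dists[r] / dists[r].sum())
        else:
            states[i] = states[i - 1]
    probs = np.full((L, 3), 0.1)
    probs[np.arange(L), states] = 0.8
    probs += rng.uniform(-0.04, 0.04, size=(L, 3))
    probs = np.clip(probs, 0.001, None)
    probs /= probs.sum(axis=1, keepdims=True)
    probs = np.round(probs, 3)
    calls = "".join("HEC"[np.argmax(row)] for row in probs)
    return probs, calls


def _pssm_track(
    rng: np.random.Generator, sequence: str, regions: RegionMap, config: GeneratorConfig
) -> tuple[np.ndarray, np.ndarray]:
    L = len(sequence)
    scores = config.pssm_mismatch_score + config.pssm_noise * rng.standard_normal((L, 20))
    aa_idx = np.array([AA_ORDER.index(aa) for aa in sequence])
    scores[np.arange(L), aa_idx] = (
        config.pssm_match_score + config.pssm_noise * rng.standard_normal(L)
    )
    scores = np.round(scores).astype(float)
    info = np.full(L, config.info_ordered)
    info[regions.disordered_mask(L)] = config.info_disordered
    info += config.info_noise * rng.standard_normal(L)
    info = np.round(np.clip(info, 0.0, None), 2)
    return scores, info


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    seq = list(sequence)
    for i in range(len(seq)):
        if rng.random() < rate:
            seq[i] = AA_ORDER[int(rng.integers(20))]
    return "".join(seq)


def generate_protein(
    config: GeneratorConfig,
    seed: int | None = None,
    protein_id: str = "syn0001",
    rng: np.random.Generator | None = None,
    sequence: str | None = None,
    regions: RegionMap | None = None,
) -> tuple[ProteinData, RegionMap]:
    """Generate one protein with all four tracks and its ground-truth regions.

    Same seed, same config => identical output. ``sequence``/``regions``
    allow regenerating tracks for a mutated family member.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    if regions is None:
        L = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        regions = _draw_regions(rng, L, config)
    else:
        L = len(sequence)
    if sequence is None:
        sequence = _draw_sequence(rng, L, regions)
    diso = _disorder_track(rng, L, regions, config)
    probs, calls = _ss_track(rng, L, regions, config)
    pssm_scores, info = _pssm_track(rng, sequence, regions, config)
    labels = ProteanLabels.from_intervals(protein_id, regions.protean, L)
    protein = ProteinData(
        record=SequenceRecord(protein_id, sequence),
        pssm=PSSMProfile(pssm_scores, info, protein_id=protein_id),
        ss=SecondaryStructureProfile(probs, calls),
        diso=DisorderProfile(diso),
        labels=labels,
    )
    return protein, regions


def generate_corpus(
    config: GeneratorConfig | None = None, out_dir: str | Path | None = None
) -> SyntheticCorpus:
    """Generate a corpus; optionally also write it to disk in all track formats."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    proteins: list[ProteinData] = []
    region_maps: dict[str, RegionMap] = {}
    families: dict[str, int] = {}
    n_families = 0
    for i in range(cfg.n_proteins):
        pid = f"syn{i + 1:04d}"
        if proteins and rng.random() < cfg.duplicate_fraction:
            parent_idx = int(rng.integers(len(proteins)))
            parent = proteins[parent_idx]
            mutated = _mutate(rng, parent.sequence, cfg.mutation_rate)
            protein, regions = generate_protein(
                cfg, protein_id=pid, rng=rng,
                sequence=mutated, regions=region_maps[parent.id],
            )
            families[pid] = families[parent.id]
        else:
            protein, regions = generate_protein(cfg, protein_id=pid, rng=rng)
            families[pid] = n_families
            n_families += 1
        proteins.append(protein)
        region_maps[pid] = regions
    corpus = SyntheticCorpus(
        proteins=proteins,
        region_maps=region_maps,
        clusters=ClusterAssignment(families),
        config=cfg,
    )
    if out_dir is not None:
        write_corpus(corpus, out_dir)
    return corpus


def generate_topography_corpus(
    n_proteins: int = 60,
    length_range: tuple[int, int] = (170, 230),
    seed: int = 0,
    valley_depth: float = 0.20,
) -> SyntheticCorpus:
    """A corpus where ONLY the disorder-topography features carry signal.

    The disorder track stays >= 0.5 everywhere (one whole-protein
    "disordered" segment, so the segment-descriptor features are per-protein
    constants), sequences and pseudo-PSSMs are composition-uniform noise,
    and the secondary-structure process is regime-independent. Every protein
    carries three flat valleys of identical depth, all wider than the
    15-residue feature window so the windowed disorder mean saturates to the
    same value inside each of them: the protean valley is wide (18-24
    residues) and the two decoys are narrow (15-16). The topographic *class*
    is therefore impure (decoy residues are valleys too) and the windowed
    mean is class-blind; the topographic run length alone separates the
    classes, by construction.
    """
    base = GeneratorConfig(seed=seed)
    rng = np.random.default_rng(seed)
    proteins: list[ProteinData] = []
    region_maps: dict[str, RegionMap] = {}
    families: dict[str, int] = {}
    uniform = np.full(20, 1 / 20)
    for i in range(n_proteins):
        pid = f"top{i + 1:04d}"
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        # three valley centres far enough apart that inter-valley peak runs
        # never fall into the protean width range
        centers = [int(0.18 * L), int(0.50 * L), int(0.82 * L)]
        protean_slot = int(rng.integers(3))
        track = np.full(L, 0.80)
        protean: list[tuple[int, int]] = []
        for slot, center in enumerate(centers):
            if slot == protean_slot:
                w = int(rng.integers(18, 25))
            else:
                w = int(rng.integers(15, 17))
            s = center - w // 2
            track[s - 1 : s - 1 + w] = 0.80 - valley_depth
            if slot == protean_slot:
                protean = [(s, s + w - 1)]
        track += rng.uniform(-0.02, 0.02, size=L)
        track = np.round(np.clip(track, 0.55, 0.95), 3)
        codes = rng.choice(20, size=L, p=uniform)
        sequence = "".join(AA_ORDER[c] for c in codes)
        regions = RegionMap(disordered=[(1, L)], protean=protean)
        pssm_scores = np.round(2.0 * rng.standard_normal((L, 20)))
        info = np.round(np.clip(1.0 + 0.2 * rng.standard_normal(L), 0, None), 2)
        probs, calls = _ss_track(
            rng, L, RegionMap(disordered=[], protean=[]),
            replace(base, ss_switch_ordered=0.10),
        )
        proteins.append(
            ProteinData(
                record=SequenceRecord(pid, sequence),
                pssm=PSSMProfile(pssm_scores, info, protein_id=pid),
                ss=SecondaryStructureProfile(probs, calls),
                diso=DisorderProfile(track),
                labels=ProteanLabels.from_intervals(pid, protean, L),
            )
        )
        region_maps[pid] = regions
        families[pid] = i
    return SyntheticCorpus(
        proteins=proteins,
        region_maps=region_maps,
        clusters=ClusterAssignment(families),
        config=base,
    )


def shuffled_labels(
    corpus: SyntheticCorpus | Sequence[ProteinData], seed: int = 0
) -> dict[str, np.ndarray]:
    """Permute pooled residue labels across the corpus (null-signal control)."""
    proteins = list(corpus)
    pooled = np.concatenate([p.labels.labels for p in proteins])
    rng = np.random.default_rng(seed)
    rng.shuffle(pooled)
    out: dict[str, np.ndarray] = {}
    offset = 0
    for p in proteins:
        out[p.id] = pooled[offset : offset + len(p)]
        offset += len(p)
    return out


# ---------------------------------------------------------------------------
# On-disk round trip


def write_pssm(protein: ProteinData, path: str | Path) -> None:
    """Write a pseudo-PSSM in the PSI-BLAST ASCII dialect (permuted columns)."""
    perm = [AA_ORDER.index(aa) for aa in PSIBLAST_ORDER]
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "           " + "  ".join(PSIBLAST_ORDER) + "   " + "  ".join(PSIBLAST_ORDER),
    ]
    for i, aa in enumerate(protein.sequence):
        scores = protein.pssm.scores[i][perm]
        row = f"{i + 1:5d} {aa} " + " ".join(f"{int(s):3d}" for s in scores)
        row += "  " + " ".join("  0" for _ in range(20))
        row += f"  {protein.pssm.info[i]:5.2f} {0.0:8.2f}"
        lines.append(row)
    lines.append("")
    Path(path).write_text("\n".join(lines))


def write_ss2(protein: ProteinData, path: str | Path) -> None:
    lines = ["# PSIPRED VFORMAT (synthetic)", ""]
    for i, (aa, call) in enumerate(zip(protein.sequence, protein.ss.calls)):
        ph, pe, pc = protein.ss.probs[i]
        lines.append(f"{i + 1:4d} {aa} {call}  {pc:6.3f} {ph:6.3f} {pe:6.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_diso(protein: ProteinData, path: str | Path) -> None:
    lines = []
    for i, aa in enumerate(protein.sequence):
        s = protein.diso.scores[i]
        mark = "*" if s >= 0.5 else "."
        lines.append(f"{i + 1:5d} {aa} {mark} {s:5.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_corpus(corpus: SyntheticCorpus, out_dir: str | Path) -> None:
    """Write FASTA, per-protein tracks, labels and clusters to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "corpus.fasta", "w") as fh:
        for p in corpus.proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p), 60):
                fh.write(p.sequence[i : i + 60] + "\n")
    for p in corpus.proteins:
        write_pssm(p, out / f"{p.id}.pssm")
        write_ss2(p, out / f"{p.id}.ss2")
        write_diso(p, out / f"{p.id}.diso")
    write_segment_labels([p.labels for p in corpus.proteins], out / "labels.tsv")
    from .io_tracks import write_clusters

    write_clusters(corpus.clusters, out / "clusters.txt")
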