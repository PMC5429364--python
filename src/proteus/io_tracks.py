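"""Readers and writers for all external per-protein track formats.

External tools produce the tracks this predictor consumes: PSI-BLAST ASCII
PSSMs (homology profile + per-position information), PSIPRED VFORMAT ``.ss2``
files (three-state secondary-structure probabilities), and DISOPRED-style
``.diso`` files (per-residue disorder probability). This module parses them
into length-checked numpy containers, plus the package's own plain-text
formats for protean-segment labels, sequence clusters, fold assignments and
per-residue predictions.

All parsers permute amino-acid columns into the fixed internal order
(alphabetical one-letter codes, see :data:`proteus._aa_tables.AA_ORDER`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from ._aa_tables import AA_ORDER, AA_INDEX, AMBIGUOUS


class FormatError(ValueError):
    """A track file is malformed or inconsistent with its sequence."""


# ---------------------------------------------------------------------------
# Containers


@dataclass
class SequenceRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("empty sequence identifier")
        if len(self.sequence) < 1:
            raise FormatError(f"empty sequence for {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PSSMProfile:
    """L x 20 substitution log-odds plus per-position information."""

    scores: np.ndarray
    info: np.ndarray
    protein_id: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.info = np.asarray(self.info, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise FormatError("PSSM scores must be L x 20")
        if self.info.shape != (self.scores.shape[0],):
            raise FormatError("PSSM info length must match score rows")
        if not (np.isfinite(self.scores).all() and np.isfinite(self.info).all()):
            raise FormatError("PSSM contains non-finite values")

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass
class SecondaryStructureProfile:
    """Three-state secondary structure: probs ordered (H, E, C) internally."""

    probs: np.ndarray
    calls: str

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 3:
            raise FormatError("secondary-structure probs must be L x 3")
        if len(self.calls) != self.probs.shape[0]:
            raise FormatError("calls length must match probability rows")
        if ((self.probs < 0) | (self.probs > 1)).any():
            raise FormatError("secondary-structure probabilities outside [0, 1]")
        sums = self.probs.sum(axis=1)
        if (np.abs(sums - 1.0) > 0.05).any():
            raise FormatError("secondary-structure rows do not sum to 1 (+-0.05)")

    def __len__(self) -> int:
        return self.probs.shape[0]


@dataclass
class DisorderProfile:
    """Per-residue disorder probabilities in [0, 1]."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise FormatError("disorder scores must be one-dimensional")
        if ((self.scores < 0) | (self.scores > 1)).any():
            raise FormatError("disorder scores outside [0, 1]")

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass
class ProteanLabels:
    """Binary per-residue target derived from 1-based inclusive intervals."""

    protein_id: str
    intervals: list[tuple[int, int]]
    labels: np.ndarray

    @classmethod
    def from_intervals(
        cls, protein_id: str, intervals: Iterable[tuple[int, int]], length: int
    ) -> "ProteanLabels":
        labels = np.zeros(length, dtype=np.int8)
        norm: list[tuple[int, int]] = []
        for start, end in intervals:
            if not (1 <= start <= end <= length):
                raise FormatError(
                    f"interval ({start}, {end}) outside [1, {length}] "
                    f"for protein {protein_id!r}"
                )
            labels[start - 1 : end] = 1
            norm.append((start, end))
        return cls(protein_id, _merge_intervals(norm), labels)

    def __len__(self) -> int:
        return self.labels.shape[0]


@dataclass
class ClusterAssignment:
    """protein_id -> integer cluster id."""

    mapping: dict[str, int] = field(default_factory=dict)

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for pid, cid in self.mapping.items():
            out.setdefault(cid, []).append(pid)
        return out

    def __getitem__(self, protein_id: str) -> int:
        return self.mapping[protein_id]

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class ProteinData:
    """All tracks of one protein, length-validated."""

    record: SequenceRecord
    pssm: PSSMProfile
    ss: SecondaryStructureProfile
    diso: DisorderProfile
    labels: ProteanLabels | None = None

    def __post_init__(self) -> None:
        validate_tracks(self.record, self.pssm, self.ss, self.diso, self.labels)

    @property
    def id(self) -> str:
        return self.record.id

    @property
    def sequence(self) -> str:
        return self.record.sequence

    def __len__(self) -> int:
        return len(self.record)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def validate_tracks(
    record: SequenceRecord,
    pssm: PSSMProfile | None = None,
    ss: SecondaryStructureProfile | None = None,
    diso: DisorderProfile | None = None,
    labels: ProteanLabels | None = None,
) -> None:
    """Assert that every provided track shares the sequence length."""
    L = len(record)
    for name, track in (("pssm", pssm), ("ss2", ss), ("diso", diso), ("labels", labels)):
        if track is not None and len(track) != L:
            raise FormatError(
                f"{name} track of {record.id!r} has length {len(track)}, "
                f"sequence has {L}"
            )


# ---------------------------------------------------------------------------
# Readers


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file; sequences are uppercased, ids must be unique."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper().replace(" ", "")))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def read_pssm(
    path: str | Path, expected_length: int | None = None, protein_id: str = ""
) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM (the ``-Q`` checkpoint dialect).

    The first 20-column block (log-odds) feeds the scores; the per-position
    information column supplies the conservation track. Columns are permuted
    from the file's amino-acid header order into the internal alphabetical
    order.
    """
    lines = Path(path).read_text().splitlines()
    header_cols: list[str] | None = None
    rows: list[list[float]] = []
    infos: list[float] = []
    for lineno, line in enumerate(lines, start=1):
        fields = line.split()
        if not fields:
            continue
        if header_cols is None:
            if len(fields) >= 20 and all(f in AA_INDEX for f in fields[:20]):
                header_cols = fields[:20]
            continue
        if not fields[0].isdigit():
            continue  # trailing K/lambda footer
        # idx, residue, 20 log-odds, 20 weight percentages, information, weight
        if len(fields) < 22:
            raise FormatError(f"{path}:{lineno}: truncated PSSM row")
        try:
            scores = [float(x) for x in fields[2:22]]
            if len(fields) >= 43:
                info = float(fields[42])
            else:
                info = float(fields[22]) if len(fields) == 23 else 0.0
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed PSSM row: {exc}") from exc
        rows.append(scores)
        infos.append(info)
    if header_cols is None or not rows:
        raise FormatError(f"{path}: no PSSM header/rows found")
    perm = [header_cols.index(aa) for aa in AA_ORDER]
    scores = np.asarray(rows, dtype=float)[:, perm]
    info = np.asarray(infos, dtype=float)
    if expected_length is not None and scores.shape[0] != expected_length:
        raise FormatError(
            f"{path}: PSSM has {scores.shape[0]} rows, expected {expected_length}"
        )
    return PSSMProfile(scores, info, protein_id=protein_id)


def read_ss2(path: str | Path) -> SecondaryStructureProfile:
    """Parse a PSIPRED VFORMAT ``.ss2`` file.

    File columns are index, residue, call, P(C), P(H), P(E); the returned
    probability matrix is reordered to (H, E, C).
    """
    probs: list[tuple[float, float, float]] = []
    calls: list[str] = []
    last_idx = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        fields = line.split()
        if not fields or fields[0].startswith("#"):
            continue
        if len(fields) != 6:
            raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
        idx = int(fields[0])
        if idx != last_idx + 1:
            raise FormatError(f"{path}:{lineno}: non-monotone residue index {idx}")
        last_idx = idx
        call = fields[2]
        if call not in "HEC":
            raise FormatError(f"{path}:{lineno}: unknown call {call!r}")
        pc, ph, pe = (float(x) for x in fields[3:6])
        probs.append((ph, pe, pc))
        calls.append(call)
    if not probs:
        raise FormatError(f"{path}: empty .ss2 body")
    return SecondaryStructureProfile(np.asarray(probs, dtype=float), "".join(calls))


def read_diso(path: str | Path) -> DisorderProfile:
    """Parse a DISOPRED-style disorder track.

    Two dialects auto-detected by column count: ``index residue mark score``
    (DISOPRED ``.diso``) or bare ``index score``. Scores are clamped to
    [0, 1]; anything outside [-0.01, 1.01] before clamping is rejected as the
    wrong kind of file.
    """
    scores: list[float] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        fields = line.split()
        if not fields or fields[0].startswith("#"):
            continue
        if len(fields) >= 4:
            raw = fields[3]
        elif len(fields) == 2:
            raw = fields[1]
        else:
            raise FormatError(f"{path}:{lineno}: unrecognised disorder row")
        try:
            val = float(raw)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad disorder score {raw!r}") from exc
        if not (-0.01 <= val <= 1.01):
            raise FormatError(
                f"{path}:{lineno}: disorder score {val} outside [0, 1] "
                "(wrong file?)"
            )
        scores.append(min(1.0, max(0.0, val)))
    if not scores:
        raise FormatError(f"{path}: empty disorder track")
    return DisorderProfile(np.asarray(scores, dtype=float))


def read_segment_labels(
    path: str | Path, sequences: Sequence[SequenceRecord]
) -> list[ProteanLabels]:
    """Read a TSV of 1-based inclusive protean intervals.

    Columns: protein_id, start, end. Proteins with no row get all-zero
    labels (pure negative examples).
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#") or line.startswith("protein_id\t"):
            continue
        fields = line.split()
        if len(fields) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns")
        pid, start, end = fields[0], int(fields[1]), int(fields[2])
        intervals.setdefault(pid, []).append((start, end))
    by_id = {rec.id: rec for rec in sequences}
    unknown = set(intervals) - set(by_id)
    if unknown:
        raise FormatError(f"{path}: intervals for unknown proteins {sorted(unknown)}")
    return [
        ProteanLabels.from_intervals(rec.id, intervals.get(rec.id, []), len(rec))
        for rec in sequences
    ]


def read_clusters(path: str | Path) -> ClusterAssignment:
    """Read BLASTclust-style output: one cluster per line, members space-separated."""
    mapping: dict[str, int] = {}
    cid = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        members = line.split()
        if not members:
            continue
        for pid in members:
            if pid in mapping:
                raise FormatError(
                    f"{path}:{lineno}: protein {pid!r} listed in two clusters"
                )
            mapping[pid] = cid
        cid += 1
    return ClusterAssignment(mapping)


# ---------------------------------------------------------------------------
# Writers (and their round-trip readers)

PREDICTION_COLUMNS = ("protein_id", "position", "residue", "proteus_score", "call")


def write_predictions(
    tracks: dict[str, tuple[str, np.ndarray]],
    path: str | Path,
    p_cut: float = 0.5,
) -> None:
    """Write per-residue prediction tracks as TSV.

    ``tracks`` maps protein_id -> (sequence, scores). Calls use the tie rule
    of the classifier: a residue is positive when score >= p_cut.
    """
    buf = io.StringIO()
    buf.write("\t".join(PREDICTION_COLUMNS) + "\n")
    for pid, (sequence, scores) in tracks.items():
        scores = np.asarray(scores, dtype=float)
        if ((scores < 0) | (scores > 1)).any():
            raise FormatError(f"prediction scores for {pid!r} outside [0, 1]")
        for i, (aa, s) in enumerate(zip(sequence, scores), start=1):
            call = 1 if s >= p_cut else 0
            buf.write(f"{pid}\t{i}\t{aa}\t{s:.4f}\t{call}\n")
    Path(path).write_text(buf.getvalue())


def read_predictions(path: str | Path) -> dict[str, tuple[str, np.ndarray]]:
    """Re-read a prediction TSV written by :func:`write_predictions`."""
    tracks: dict[str, list[tuple[str, float]]] = {}
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != "\t".join(PREDICTION_COLUMNS):
        raise FormatError(f"{path}: missing prediction header")
    for line in lines[1:]:
        pid, pos, aa, score, _call = line.split("\t")
        tracks.setdefault(pid, []).append((aa, float(score)))
    return {
        pid: ("".join(a for a, _ in rows), np.array([s for _, s in rows]))
        for pid, rows in tracks.items()
    }


def write_clusters(clusters: ClusterAssignment, path: str | Path) -> None:
    lines = [" ".join(sorted(members)) for _, members in sorted(clusters.members().items())]
    Path(path).write_text("\n".join(lines) + "\n")


def write_segment_labels(labels: Sequence[ProteanLabels], path: str | Path) -> None:
    buf = ["protein_id\tstart\tend"]
    for lab in labels:
        for start, end in lab.intervals:
            buf.append(f"{lab.protein_id}\t{start}\t{end}")
    Path(path).write_text("\n".join(buf) + "\n")


def write_fold_assignment(folds: dict[str, int], path: str | Path) -> None:
    buf = ["protein_id\tfold"]
    buf += [f"{pid}\t{f}" for pid, f in sorted(folds.items())]
    Path(path).write_text("\n".join(buf) + "\n")


def read_fold_assignment(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    for line in Path(path).read_text().splitlines()[1:]:
        if line.strip():
            pid, f = line.split("\t")
            out[pid] = int(f)
    return out


# ---------------------------------------------------------------------------
# Corpus loading


def load_corpus(
    directory: str | Path,
    fasta_name: str = "corpus.fasta",
    labels_name: str = "labels.tsv",
) -> list[ProteinData]:
    """Load a directory of tracks: FASTA + per-protein .pssm/.ss2/.diso files.

    Track files are named ``<protein_id>.pssm`` etc. Labels are optional.
    """
    directory = Path(directory)
    records = read_fasta(directory / fasta_name)
    labels_path = directory / labels_name
    labels: dict[str, ProteanLabels] = {}
    if labels_path.exists():
        labels = {lab.protein_id: lab for lab in read_segment_labels(labels_path, records)}
    corpus = []
    for rec in records:
        pssm_path = directory / f"{rec.id}.pssm"
        ss2_path = directory / f"{rec.id}.ss2"
        diso_path = directory / f"{rec.id}.diso"
        for p in (pssm_path, ss2_path, diso_path):
            if not p.exists():
                raise FormatError(f"missing track file {p} for protein {rec.id!r}")
        corpus.append(
            ProteinData(
                record=rec,
                pssm=read_pssm(pssm_path, expected_length=len(rec), protein_id=rec.id),
                ss=read_ss2(ss2_path),
                diso=read_diso(diso_path),
                labels=labels.get(rec.id),
            )
        )
    return corpus
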