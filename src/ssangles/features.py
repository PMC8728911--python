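"""Per-residue feature assembly, sliding-window encoding, and normalization.

Each residue carries up to 56 features, concatenated in a fixed block order:

    [ SS8 one-hot (8) | PSSM (20) | 7PCP (7) | HMM (20, optional) | ASA (1, optional) ]

A configuration is named by a four-character AHIW code:
A in {Y,N} — use the ASA feature; H in {Y,N} — use the HMM block;
I in {R,Z} — [0,1]-range or Z-score input encoding; W in {5,9} — window size.
The window stacks the per-residue vectors of the W residues centred on each
position (floor(W/2) before and after); positions beyond the chain contribute
all-zero blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import AngleTable

__all__ = [
    "SS8_ALPHABET",
    "AA_ORDER",
    "PCP_TABLE",
    "Ahiw",
    "ProteinRecord",
    "ResidueFeatures",
    "FeatureMatrix",
    "NormalizationStats",
    "one_hot_ss8",
    "assemble_residue_features",
    "residue_feature_matrix",
    "window_encode",
    "build_feature_matrix",
    "fit_normalization",
    "apply_normalization",
    "read_pssm",
    "read_hhm",
    "read_ss8_fasta",
    "read_fasta_sequence",
    "read_asa_tsv",
    "load_records",
]

#: fixed 8-state secondary-structure alphabet; one-hot position = index here
SS8_ALPHABET = "HGIEBTSC"

#: canonical amino-acid column order (PSI-BLAST PSSM column order)
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: HHsuite HHM match-emission column order (alphabetical one-letter codes)
HHM_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

# Seven physicochemical property constants per amino acid:
# steric parameter, polarizability, volume, hydrophobicity, isoelectric point,
# helix probability, sheet probability.  Values follow the common literature
# parameterisation used for profile-based angle predictors.
PCP_TABLE: dict[str, tuple[float, ...]] = {
    "A": (1.28, 0.05, 1.00, 0.31, 6.11, 0.42, 0.23),
    "R": (2.34, 0.29, 6.13, -1.01, 10.74, 0.36, 0.25),
    "N": (1.60, 0.13, 2.95, -0.60, 6.52, 0.21, 0.22),
    "D": (1.60, 0.11, 2.78, -0.77, 2.95, 0.25, 0.20),
    "C": (1.77, 0.13, 2.43, 1.54, 6.35, 0.17, 0.41),
    "Q": (1.56, 0.18, 3.95, -0.22, 5.65, 0.36, 0.25),
    "E": (1.56, 0.15, 3.78, -0.64, 3.09, 0.42, 0.21),
    "G": (0.00, 0.00, 0.00, 0.00, 6.07, 0.13, 0.15),
    "H": (2.99, 0.23, 4.66, 0.13, 7.69, 0.27, 0.30),
    "I": (4.19, 0.19, 4.00, 1.80, 6.04, 0.30, 0.45),
    "L": (2.59, 0.19, 4.00, 1.70, 6.04, 0.39, 0.31),
    "K": (1.89, 0.22, 4.77, -0.99, 9.99, 0.32, 0.27),
    "M": (2.35, 0.22, 4.43, 1.23, 5.71, 0.38, 0.32),
    "F": (2.94, 0.29, 5.89, 1.79, 5.67, 0.30, 0.38),
    "P": (2.67, 0.00, 2.72, 0.72, 6.80, 0.13, 0.34),
    "S": (1.31, 0.06, 1.60, -0.04, 5.70, 0.20, 0.28),
    "T": (3.03, 0.11, 2.60, 0.26, 5.60, 0.21, 0.36),
    "W": (3.21, 0.41, 8.08, 2.25, 5.94, 0.32, 0.42),
    "Y": (2.94, 0.30, 6.47, 0.96, 5.66, 0.25, 0.41),
    "V": (3.67, 0.14, 3.00, 1.22, 6.02, 0.27, 0.49),
}


class InvalidStateError(ValueError):
    """Unknown 8-state secondary-structure character."""


class MissingFeatureError(ValueError):
    """A block required by the AHIW setting is absent."""


def one_hot_ss8(state: str) -> np.ndarray:
    """8-vector with a single 1 at the position of ``state`` in ``HGIEBTSC``."""
    idx = SS8_ALPHABET.find(state)
    if idx < 0:
        raise InvalidStateError(
            f"unknown SS8 state {state!r}; expected one of {SS8_ALPHABET!r}"
        )
    v = np.zeros(8)
    v[idx] = 1.0
    return v


@dataclass(frozen=True)
class Ahiw:
    """Four-character feature/encoding configuration (e.g. ``YYR9``)."""

    use_asa: bool
    use_hmm: bool
    encoding: str  # "range" | "zscore"
    window: int    # 5 | 9

    def __post_init__(self) -> None:
        if self.encoding not in ("range", "zscore"):
            raise ValueError(f"encoding must be 'range' or 'zscore', got {self.encoding!r}")
        if self.window not in (5, 9):
            raise ValueError(f"window must be 5 or 9, got {self.window}")

    @classmethod
    def parse(cls, name: str) -> "Ahiw":
        if len(name) != 4 or name[0] not in "YN" or name[1] not in "YN" \
                or name[2] not in "RZ" or name[3] not in "59":
            raise ValueError(f"invalid AHIW setting name {name!r}")
        return cls(
            use_asa=name[0] == "Y",
            use_hmm=name[1] == "Y",
            encoding="range" if name[2] == "R" else "zscore",
            window=int(name[3]),
        )

    @property
    def name(self) -> str:
        return (
            ("Y" if self.use_asa else "N")
            + ("Y" if self.use_hmm else "N")
            + ("R" if self.encoding == "range" else "Z")
            + str(self.window)
        )

    @property
    def residue_width(self) -> int:
        """Feature count per residue under this setting (35..56)."""
        return 8 + 20 + 7 + (20 if self.use_hmm else 0) + (1 if self.use_asa else 0)

    def block_names(self) -> list[str]:
        names = ["ss8", "pssm", "pcp7"]
        if self.use_hmm:
            names.append("hmm")
        if self.use_asa:
            names.append("asa")
        return names


@dataclass
class ResidueFeatures:
    """One residue's concatenated feature vector plus block provenance."""

    vector: np.ndarray
    blocks: tuple[str, ...]


def assemble_residue_features(
    ss8: str,
    pssm: np.ndarray,
    pcp7: np.ndarray,
    hmm: np.ndarray | None,
    asa: float | None,
    setting: Ahiw,
) -> ResidueFeatures:
    """Concatenate one residue's blocks in the fixed order [ss8, pssm, pcp7, hmm?, asa?]."""
    pssm = np.asarray(pssm, float)
    pcp7 = np.asarray(pcp7, float)
    if pssm.shape != (20,):
        raise ValueError(f"pssm block must have 20 entries, got {pssm.shape}")
    if pcp7.shape != (7,):
        raise ValueError(f"pcp7 block must have 7 entries, got {pcp7.shape}")
    parts = [one_hot_ss8(ss8), pssm, pcp7]
    if setting.use_hmm:
        if hmm is None:
            raise MissingFeatureError("setting requires the HMM block but it is absent")
        hmm = np.asarray(hmm, float)
        if hmm.shape != (20,):
            raise ValueError(f"hmm block must have 20 entries, got {hmm.shape}")
        parts.append(hmm)
    if setting.use_asa:
        if asa is None:
            raise MissingFeatureError("setting requires the ASA block but it is absent")
        parts.append(np.array([float(asa)]))
    return ResidueFeatures(np.concatenate(parts), tuple(setting.block_names()))


@dataclass
class ProteinRecord:
    """All per-protein inputs a model needs, in memory.

    ``pssm``/``hmm`` are (L, 20) arrays in AA_ORDER column order; ``asa`` is
    length L.  ``ss8_pred`` drives model routing; ``ss8_true`` (when known)
    drives evaluation stratification.
    """

    protein_id: str
    sequence: str
    ss8_pred: str
    ss8_true: str | None = None
    pssm: np.ndarray | None = None
    hmm: np.ndarray | None = None
    asa: np.ndarray | None = None
    angles: AngleTable | None = None
    chain: object | None = None  # BackboneChain when coordinates are known

    def __len__(self) -> int:
        return len(self.sequence)

    def pcp_matrix(self) -> np.ndarray:
        return np.array([PCP_TABLE[aa] for aa in self.sequence])


def residue_feature_matrix(record: ProteinRecord, setting: Ahiw) -> np.ndarray:
    """(L, residue_width) raw per-residue feature matrix for one protein."""
    L = len(record)
    if record.pssm is None:
        raise MissingFeatureError(f"protein {record.protein_id}: PSSM block absent")
    onehot = np.zeros((L, 8))
    for i, s in enumerate(record.ss8_pred):
        onehot[i] = one_hot_ss8(s)
    parts = [onehot, np.asarray(record.pssm, float), record.pcp_matrix()]
    if setting.use_hmm:
        if record.hmm is None:
            raise MissingFeatureError(f"protein {record.protein_id}: HMM block absent")
        parts.append(np.asarray(record.hmm, float))
    if setting.use_asa:
        if record.asa is None:
            raise MissingFeatureError(f"protein {record.protein_id}: ASA block absent")
        parts.append(np.asarray(record.asa, float).reshape(-1, 1))
    return np.concatenate(parts, axis=1)


def window_encode(per_residue: np.ndarray, window: int) -> np.ndarray:
    """Stack each residue's W-window of per-residue vectors into one row.

    Row i is the concatenation of rows i - W//2 ... i + W//2 of ``per_residue``;
    positions outside the chain contribute zero blocks.
    """
    if window % 2 != 1:
        raise ValueError("window size must be odd")
    per_residue = np.asarray(per_residue, float)
    if per_residue.ndim != 2 or per_residue.shape[0] == 0:
        raise ValueError("per-residue matrix must be non-empty and 2-D")
    L, d = per_residue.shape
    half = window // 2
    padded = np.zeros((L + 2 * half, d))
    padded[half : half + L] = per_residue
    cols = [padded[k : k + L] for k in range(window)]
    return np.concatenate(cols, axis=1)


@dataclass
class FeatureMatrix:
    """Windowed feature rows aligned with per-residue labels and provenance."""

    X: np.ndarray
    setting: Ahiw
    ss3: np.ndarray            # per-row 3-state label ("helix"/"sheet"/"coil")
    protein_ids: np.ndarray    # per-row protein identifier
    residue_index: np.ndarray  # per-row 1-based residue index

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        for name in ("ss3", "protein_ids", "residue_index"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} not aligned with feature rows")
        expect = self.setting.residue_width * self.setting.window
        if self.X.shape[1] != expect:
            raise ValueError(
                f"feature width {self.X.shape[1]} != residue_width*W = {expect}"
            )

    def __len__(self) -> int:
        return self.X.shape[0]

    def take(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.X[idx], self.setting, self.ss3[idx],
            self.protein_ids[idx], self.residue_index[idx],
        )

    def column_names(self) -> list[str]:
        widths = {"ss8": 8, "pssm": 20, "pcp7": 7, "hmm": 20, "asa": 1}
        per_res = [
            f"{blk}_{j}" for blk in self.setting.block_names() for j in range(widths[blk])
        ]
        half = self.setting.window // 2
        return [f"w{o:+d}.{c}" for o in range(-half, half + 1) for c in per_res]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.X, columns=self.column_names())
        df.insert(0, "protein_id", self.protein_ids)
        df.insert(1, "residue_index", self.residue_index)
        df.insert(2, "ss3", self.ss3)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def build_feature_matrix(records: list[ProteinRecord], setting: Ahiw) -> FeatureMatrix:
    """Window-encode every record under one AHIW setting and stack the rows."""
    from .ss_router import map_ss8_to_ss3

    mats, ss3, pids, ridx = [], [], [], []
    for rec in records:
        raw = residue_feature_matrix(rec, setting)
        mats.append(window_encode(raw, setting.window))
        ss3.extend(map_ss8_to_ss3(s) for s in rec.ss8_pred)
        pids.extend([rec.protein_id] * len(rec))
        ridx.extend(range(1, len(rec) + 1))
    return FeatureMatrix(
        np.concatenate(mats, axis=0),
        setting,
        np.array(ss3),
        np.array(pids),
        np.array(ridx),
    )


@dataclass
class NormalizationStats:
    """Per-column training-set statistics for range or Z-score encoding."""

    mode: str                 # "range" | "zscore"
    lo: np.ndarray            # x_min (range) or mu (zscore)
    hi: np.ndarray            # x_max (range) or sigma (zscore)
    fitted_on: str = ""

    @property
    def n_columns(self) -> int:
        return len(self.lo)


def fit_normalization(train, mode: str, fitted_on: str = "") -> NormalizationStats:
    """Fit per-column min/max (range) or mean/sd (zscore, population sd) statistics."""
    X = train.X if isinstance(train, FeatureMatrix) else np.asarray(train, float)
    if X.shape[0] == 0:
        raise ValueError("cannot fit normalization on an empty matrix")
    if mode == "range":
        return NormalizationStats("range", X.min(axis=0), X.max(axis=0), fitted_on)
    if mode == "zscore":
        return NormalizationStats("zscore", X.mean(axis=0), X.std(axis=0), fitted_on)
    raise ValueError(f"unknown normalization mode {mode!r}")


def apply_normalization(m, stats: NormalizationStats, mode: str | None = None):
    """x' = (x - x_min)/(x_max - x_min) or (x - mu)/sigma, column-wise.

    Degenerate columns (x_max == x_min, or sigma == 0) map to 0.  Values are
    not clipped: test-set values outside the training range may leave [0, 1].
    """
    mode = mode or stats.mode
    if mode != stats.mode:
        raise ValueError(f"stats were fitted in {stats.mode!r} mode, not {mode!r}")
    X = m.X if isinstance(m, FeatureMatrix) else np.asarray(m, float)
    if X.shape[1] != stats.n_columns:
        raise ValueError(
            f"layout mismatch: matrix has {X.shape[1]} columns, stats {stats.n_columns}"
        )
    if mode == "range":
        span = stats.hi - stats.lo
        denom = np.where(span == 0, 1.0, span)
        Xn = (X - stats.lo) / denom
        Xn[:, span == 0] = 0.0
    else:
        denom = np.where(stats.hi == 0, 1.0, stats.hi)
        Xn = (X - stats.lo) / denom
        Xn[:, stats.hi == 0] = 0.0
    if isinstance(m, FeatureMatrix):
        return FeatureMatrix(Xn, m.setting, m.ss3, m.protein_ids, m.residue_index)
    return Xn


# ---------------------------------------------------------------------------
# Readers for the standard per-residue input file formats
# ---------------------------------------------------------------------------

def read_pssm(path) -> np.ndarray:
    """Parse a PSI-BLAST ASCII PSSM into an (L, 20) log-odds array (AA_ORDER).

    Skips the header and the trailing information-content/statistics lines;
    keeps the first 20 numeric columns of each residue row.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 22 and parts[0].isdigit() and len(parts[1]) == 1:
                try:
                    vals = [float(v) for v in parts[2:22]]
                except ValueError:
                    continue
                rows.append(vals)
    if not rows:
        raise ValueError(f"no PSSM rows found in {path}")
    return np.array(rows)


def read_hhm(path) -> np.ndarray:
    """Parse an HHsuite HHM profile into (L, 20) match-emission frequencies.

    The format stores -1000*log2(p) integers ('*' meaning p = 0); columns are
    reordered from the format's alphabetical order to AA_ORDER.
    """
    with open(path) as fh:
        lines = fh.readlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.startswith("HMM\t") or l.startswith("HMM "))
    except StopIteration:
        raise ValueError(f"no HMM block in {path}")
    header_order = lines[start].split()[1:21]
    rows = []
    # scan forward: emission lines start with "<AA> <index>"
    for line in lines[start + 1:]:
        parts = line.split()
        if line.startswith("//"):
            break
        if len(parts) >= 22 and len(parts[0]) == 1 and parts[0].isalpha() and parts[1].isdigit():
            rows.append(
                [np.inf if tok == "*" else float(tok) for tok in parts[2:22]]
            )
    if not rows:
        raise ValueError(f"no emission rows found in {path}")
    scores = np.array(rows)
    arr = np.where(np.isinf(scores), 0.0, 2.0 ** (-scores / 1000.0))
    order = [header_order.index(aa) for aa in AA_ORDER]
    return arr[:, order]


def _read_single_fasta(path) -> str:
    from Bio import SeqIO

    recs = list(SeqIO.parse(str(path), "fasta"))
    if not recs:
        raise ValueError(f"no FASTA record in {path}")
    return str(recs[0].seq)


def read_ss8_fasta(path) -> str:
    """Read an 8-state SS prediction stored as a single-sequence FASTA-like file."""
    s = _read_single_fasta(path)
    bad = set(s) - set(SS8_ALPHABET)
    if bad:
        raise InvalidStateError(f"invalid SS8 characters {sorted(bad)} in {path}")
    return s


def read_fasta_sequence(path) -> str:
    return _read_single_fasta(path)


def read_asa_tsv(path) -> np.ndarray:
    """Read per-residue accessible surface area (columns: residue_index, asa)."""
    df = pd.read_csv(path, sep="\t")
    return df["asa"].to_numpy(float)


def load_records(directory) -> list[ProteinRecord]:
    """Load every protein of a dataset directory written by the simulator/CLI.

    Expects, per protein id P: P.fasta, P.ss8, P.ss8_true (optional), P.pssm,
    P.hhm (optional), P.asa.tsv (optional), P.angles.tsv (optional).
    """
    from pathlib import Path

    directory = Path(directory)
    records = []
    for fasta in sorted(directory.glob("*.fasta")):
        pid = fasta.stem
        seq = read_fasta_sequence(fasta)
        rec = ProteinRecord(
            protein_id=pid,
            sequence=seq,
            ss8_pred=read_ss8_fasta(directory / f"{pid}.ss8"),
            pssm=read_pssm(directory / f"{pid}.pssm"),
        )
        p = directory / f"{pid}.ss8_true"
        if p.exists():
            rec.ss8_true = read_ss8_fasta(p)
        p = directory / f"{pid}.hhm"
        if p.exists():
            rec.hmm = read_hhm(p)
        p = directory / f"{pid}.asa.tsv"
        if p.exists():
            rec.asa = read_asa_tsv(p)
        p = directory / f"{pid}.angles.tsv"
        if p.exists():
            rec.angles = AngleTable.from_tsv(p, protein_id=pid)
        records.append(rec)
    if not records:
        raise ValueError(f"no protein records found in {directory}")
    return records
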