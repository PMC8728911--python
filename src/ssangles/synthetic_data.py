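"""Self-contained synthetic protein datasets with planted, learnable structure.

The generator emulates the statistical shape of the real inputs the predictor
consumes, without any downloads:

* secondary structure is drawn as segments (helix/sheet/coil) whose residue
  fractions follow the configured stationary mix (defaults near the 38/23/39
  helix/sheet/coil split typical of globular-protein datasets);
* phi/psi are sampled from class-conditional Ramachandran-like distributions
  (tight basins for helix and sheet, a broad mixture for coil);
* coordinates are built from the sampled torsions with the chain builder, and
  theta/tau are then measured from those coordinates, closing the loop;
* PSSM-like and HMM-like profile columns are smooth low-order trigonometric
  functions of the residue's four angles (sin/cos of phi, psi, tau, and the
  scaled theta) with class-specific coefficients, plus configurable noise —
  an invertible planted signal that a fully-connected regressor can learn for
  every angle type;
* the predicted SS8 string equals the true one with per-residue corruption at
  a configurable error rate.

Feature values are quantized exactly as their file formats quantize them
(integer log-odds for the PSSM, integer -1000*log2(p) for the HMM emissions,
two decimals for ASA), so in-memory records equal their file round-trips.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .builder import build_backbone, default_library
from .features import AA_ORDER, HHM_AA_ORDER, ProteinRecord, SS8_ALPHABET
from .geometry import AngleTable, compute_backbone_angles, write_pdb

__all__ = [
    "GeneratorConfig",
    "generate_protein",
    "simulate_records",
    "generate_dataset",
    "write_pssm",
    "write_hhm",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: SS8 letter frequencies within each 3-state class
SS8_WITHIN_CLASS = {
    "helix": (("H", 0.85), ("G", 0.10), ("I", 0.05)),
    "sheet": (("E", 0.90), ("B", 0.10)),
    "coil": (("C", 0.50), ("T", 0.30), ("S", 0.20)),
}

#: class phase offsets (degrees) making the angle->feature maps class-divergent
CLASS_PHASE = {"helix": 0.0, "sheet": 120.0, "coil": 240.0}

# fixed internal seeds for the structural link-function coefficients; these are
# constants of the generator, not part of a dataset's random state
_PSSM_COEF_SEED = 777001
_HMM_COEF_SEED = 777002

_PSSM_SCALE = 12  # integer log-odds amplitude of the planted PSSM signal


def _mixture(*components):
    return tuple(components)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-protein generator.

    Angle distributions are mixtures of wrapped normals given as
    (weight, mean_deg, sd_deg) components per class and angle.
    """

    n_proteins: int = 60
    length_range: tuple[int, int] = (40, 80)
    #: target stationary residue fractions per class
    class_fractions: dict = field(
        default_factory=lambda: {"helix": 0.38, "sheet": 0.23, "coil": 0.39}
    )
    #: mean segment length (residues) per class
    segment_mean_length: dict = field(
        default_factory=lambda: {"helix": 9.0, "sheet": 5.0, "coil": 6.0}
    )
    phi_dist: dict = field(
        default_factory=lambda: {
            "helix": _mixture((1.0, -63.0, 6.0)),
            "sheet": _mixture((1.0, -120.0, 6.0)),
            "coil": _mixture((0.6, -90.0, 25.0), (0.4, 75.0, 20.0)),
        }
    )
    psi_dist: dict = field(
        default_factory=lambda: {
            "helix": _mixture((1.0, -42.0, 6.0)),
            "sheet": _mixture((1.0, 135.0, 6.0)),
            "coil": _mixture((0.5, 130.0, 30.0), (0.3, -20.0, 25.0), (0.2, 60.0, 30.0)),
        }
    )
    #: noise scale, as a fraction of each feature family's signal amplitude
    feature_noise: float = 0.1
    #: per-residue probability that the predicted SS8 letter is corrupted
    ss_error_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        lo, hi = self.length_range
        if lo < 5 or hi < lo:
            raise ValueError("length_range must satisfy 5 <= lo <= hi")
        if not (0.0 <= self.ss_error_rate < 1.0):
            raise ValueError("ss_error_rate must be in [0, 1)")
        if self.feature_noise < 0:
            raise ValueError("feature_noise must be non-negative")
        for dist in (self.phi_dist, self.psi_dist):
            for comps in dist.values():
                for w, mu, sd in comps:
                    if sd <= 0:
                        raise ValueError("all angle spreads must be positive")


def _segment_class_probs(cfg: GeneratorConfig) -> dict:
    # segment class probability ~ residue fraction / mean segment length, so the
    # stationary residue mix matches the configured fractions
    raw = {
        c: cfg.class_fractions[c] / cfg.segment_mean_length[c]
        for c in ("helix", "sheet", "coil")
    }
    z = sum(raw.values())
    return {c: v / z for c, v in raw.items()}


def _sample_mixture(comps, rng) -> float:
    w = np.array([c[0] for c in comps])
    k = rng.choice(len(comps), p=w / w.sum())
    _, mu, sd = comps[k]
    from .geometry import wrap_angle

    return float(wrap_angle(rng.normal(mu, sd)))


N_BASIS = 9


def _link_coefficients(seed: int) -> dict:
    """Fixed coefficient table for the angle->feature maps.

    The same matrix is shared by all three classes; divergence comes from the
    class-specific phase offsets, so an identical feature pattern corresponds
    to *different* angles in different classes (the maps genuinely conflict,
    and only the secondary-structure track resolves the ambiguity).
    """
    r = np.random.default_rng(seed)
    A = r.uniform(-1.0, 1.0, size=(20, N_BASIS))
    A /= np.abs(A).sum(axis=1, keepdims=True)  # |row . basis| <= 1
    return {cls_name: A for cls_name in ("helix", "sheet", "coil")}


_PSSM_COEFS = _link_coefficients(_PSSM_COEF_SEED)
_HMM_COEFS = _link_coefficients(_HMM_COEF_SEED)


def _trig_basis(
    phi_deg: np.ndarray,
    psi_deg: np.ndarray,
    theta_deg: np.ndarray,
    tau_deg: np.ndarray,
    phase_deg: float,
) -> np.ndarray:
    """Per-residue bounded basis carrying an invertible signal for all four angles.

    theta/tau are the angles measured from the built coordinates (0 where a
    terminus leaves them undefined), so every regression target is recoverable
    from its own residue's features.
    """
    p = np.radians(phi_deg + phase_deg)
    s = np.radians(psi_deg + phase_deg)
    t = np.radians(np.nan_to_num(tau_deg) + phase_deg)
    th = np.nan_to_num(theta_deg, nan=90.0) / 90.0 - 1.0  # [0,180] -> [-1,1]
    return np.stack(
        [np.sin(p), np.cos(p), np.sin(s), np.cos(s),
         np.sin(t), np.cos(t), th,
         np.sin(p + s), np.cos(p - s)],
        axis=1,
    )


def _quantize_hhm_prob(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities -> integer -1000*log2(p) scores and back (format precision)."""
    p = np.clip(p, 2.0**-20, 1.0)
    scores = np.rint(-1000.0 * np.log2(p)).astype(int)
    return scores, 2.0 ** (-scores / 1000.0)


def generate_protein(cfg: GeneratorConfig, rng: np.random.Generator) -> ProteinRecord:
    """Draw one synthetic protein: SS, angles, coordinates, and feature blocks."""
    cfg.validate()
    L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
    probs = _segment_class_probs(cfg)
    classes = ("helix", "sheet", "coil")
    pvec = np.array([probs[c] for c in classes])

    ss3 = []
    while len(ss3) < L:
        cls_name = classes[rng.choice(3, p=pvec)]
        seg_len = 1 + rng.poisson(cfg.segment_mean_length[cls_name] - 1.0)
        ss3.extend([cls_name] * seg_len)
    ss3 = ss3[:L]

    ss8 = []
    for c in ss3:
        letters, weights = zip(*SS8_WITHIN_CLASS[c])
        ss8.append(letters[rng.choice(len(letters), p=np.array(weights) / sum(weights))])
    ss8_true = "".join(ss8)

    sequence = "".join(AA20[k] for k in rng.integers(0, 20, size=L))
    phi = np.array([_sample_mixture(cfg.phi_dist[c], rng) for c in ss3])
    psi = np.array([_sample_mixture(cfg.psi_dist[c], rng) for c in ss3])

    chain = build_backbone(sequence, phi, psi, default_library())
    measured = compute_backbone_angles(chain)
    # store the sampled phi/psi (termini undefined) plus measured theta/tau
    phi_t = phi.copy()
    psi_t = psi.copy()
    phi_t[0] = np.nan
    psi_t[-1] = np.nan
    angles = AngleTable(phi_t, psi_t, measured.theta, measured.tau, sequence)

    # planted features, quantized at the precision of their file formats
    pssm_rows = np.empty((L, 20))
    hmm_rows = np.empty((L, 20))
    for c in classes:
        idx = np.array([i for i, x in enumerate(ss3) if x == c], dtype=int)
        if len(idx) == 0:
            continue
        basis = _trig_basis(
            phi[idx], psi[idx], measured.theta[idx], measured.tau[idx], CLASS_PHASE[c]
        )
        raw = basis @ _PSSM_COEFS[c].T  # (n, 20), in [-1, 1]
        if cfg.feature_noise > 0:
            raw = raw + rng.normal(0.0, cfg.feature_noise, raw.shape)
        pssm_rows[idx] = np.clip(np.rint(_PSSM_SCALE * raw), -16, 16)
        logits = 2.5 * (basis @ _HMM_COEFS[c].T)
        if cfg.feature_noise > 0:
            logits = logits + rng.normal(0.0, 2.5 * cfg.feature_noise, logits.shape)
        expl = np.exp(logits - logits.max(axis=1, keepdims=True))
        p = expl / expl.sum(axis=1, keepdims=True)
        _, pq = _quantize_hhm_prob(p)
        hmm_rows[idx] = pq

    asa_base = {"helix": 35.0, "sheet": 25.0, "coil": 60.0}
    asa = np.array(
        [
            asa_base[c] + 10.0 * np.sin(np.radians(f)) + 10.0 * np.cos(np.radians(s))
            for c, f, s in zip(ss3, phi, psi)
        ]
    )
    if cfg.feature_noise > 0:
        asa = asa + rng.normal(0.0, 50.0 * cfg.feature_noise, L)
    asa = np.round(np.clip(asa, 0.0, 250.0), 2)

    pred = list(ss8_true)
    if cfg.ss_error_rate > 0:
        flip = rng.random(L) < cfg.ss_error_rate
        for i in np.flatnonzero(flip):
            alternatives = [s for s in SS8_ALPHABET if s != pred[i]]
            pred[i] = alternatives[rng.integers(0, len(alternatives))]
    ss8_pred = "".join(pred)

    rec = ProteinRecord(
        protein_id="",
        sequence=sequence,
        ss8_pred=ss8_pred,
        ss8_true=ss8_true,
        pssm=pssm_rows,
        hmm=hmm_rows,
        asa=asa,
        angles=angles,
        chain=chain,  # kept for round-trip checks and PDB output
    )
    return rec


def simulate_records(
    cfg: GeneratorConfig, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
) -> dict[str, list[ProteinRecord]]:
    """Generate ``cfg.n_proteins`` proteins and split them train/val/test.

    Splits are disjoint by construction; the same config and seed reproduce
    the identical dataset.
    """
    cfg.validate()
    if sum(fractions) > 1.0 + 1e-9 or any(f < 0 for f in fractions):
        raise ValueError("split fractions must be non-negative and sum to at most 1")
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_proteins)
    records = []
    for i, child in enumerate(children):
        rec = generate_protein(cfg, np.random.default_rng(child))
        rec.protein_id = f"SYN{i:04d}"
        records.append(rec)
    n = cfg.n_proteins
    n_tr = int(round(fractions[0] * n))
    n_va = int(round(fractions[1] * n))
    n_te = min(int(round(fractions[2] * n)), n - n_tr - n_va)
    return {
        "train": records[:n_tr],
        "val": records[n_tr : n_tr + n_va],
        "test": records[n_tr + n_va : n_tr + n_va + n_te],
    }


# ---------------------------------------------------------------------------
# File-format writers (the exact formats the feature readers parse)
# ---------------------------------------------------------------------------

def _write_fasta(path, pid: str, seq: str) -> None:
    Path(path).write_text(f">{pid}\n{seq}\n")


def write_pssm(path, pid: str, sequence: str, pssm: np.ndarray) -> None:
    """Write an integer log-odds matrix in PSI-BLAST ASCII PSSM layout."""
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed"
        " percentages rounded down, information per position, and relative"
        " weight of gapless real matches to pseudocounts",
        "           " + "   ".join(AA_ORDER) + "   " + "   ".join(AA_ORDER),
    ]
    for i, aa in enumerate(sequence):
        scores = " ".join(f"{int(v):3d}" for v in pssm[i])
        pct = " ".join(f"{0:3d}" for _ in range(20))
        lines.append(f"{i + 1:5d} {aa}  {scores}  {pct}  0.00 0.00")
    lines += ["", "                      K         Lambda", "Standard Ungapped    0.1337     0.3177", ""]
    Path(path).write_text("\n".join(lines))


def write_hhm(path, pid: str, sequence: str, hmm_probs: np.ndarray) -> None:
    """Write match-emission probabilities in HHsuite HHM layout.

    Probabilities are stored as integer -1000*log2(p); the input is expected
    to already be quantized at that precision (AA_ORDER column order).
    """
    L = len(sequence)
    order = [AA_ORDER.index(aa) for aa in HHM_AA_ORDER]
    lines = [
        "HHsearch 1.5",
        f"NAME  {pid}",
        f"LENG  {L} match states, {L} columns in multiple alignment",
        "",
        "#",
        "NULL   3706 5728 4211 4064 4839 3729 4763 4308 4069 3323 5509 4640 4464 4937 4285 4423 3815 3783 6325 4665",
        "HMM    " + "\t".join(HHM_AA_ORDER),
        "       M->M\tM->I\tM->D\tI->M\tI->I\tD->M\tD->D\tNeff\tNeff_I\tNeff_D",
        "       0\t*\t*\t0\t*\t0\t*\t*\t*\t*",
    ]
    for i, aa in enumerate(sequence):
        p = hmm_probs[i][order]
        toks = []
        for v in p:
            if v <= 2.0**-20:
                toks.append("*")
            else:
                toks.append(str(int(round(-1000.0 * np.log2(v)))))
        lines.append(f"{aa} {i + 1}\t" + "\t".join(toks) + f"\t{i + 1}")
        lines.append("       0\t*\t*\t0\t*\t0\t*\t*\t*\t*")
    lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_asa(path, asa: np.ndarray) -> None:
    lines = ["residue_index\tasa"]
    lines += [f"{i + 1}\t{v:.2f}" for i, v in enumerate(asa)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_record(rec: ProteinRecord, directory: Path) -> list[Path]:
    """Write one protein's full file set; returns the paths written."""
    directory.mkdir(parents=True, exist_ok=True)
    pid = rec.protein_id
    paths = []

    def out(name):
        p = directory / name
        paths.append(p)
        return p

    _write_fasta(out(f"{pid}.fasta"), pid, rec.sequence)
    _write_fasta(out(f"{pid}.ss8"), pid, rec.ss8_pred)
    if rec.ss8_true is not None:
        _write_fasta(out(f"{pid}.ss8_true"), pid, rec.ss8_true)
    write_pssm(out(f"{pid}.pssm"), pid, rec.sequence, rec.pssm)
    if rec.hmm is not None:
        write_hhm(out(f"{pid}.hhm"), pid, rec.sequence, rec.hmm)
    if rec.asa is not None:
        _write_asa(out(f"{pid}.asa.tsv"), rec.asa)
    if rec.angles is not None:
        rec.angles.to_tsv(out(f"{pid}.angles.tsv"))
    chain = getattr(rec, "chain", None)
    if chain is not None:
        write_pdb(chain, out(f"{pid}.pdb"))
    return paths


def generate_dataset(
    cfg: GeneratorConfig,
    out_dir,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> dict:
    """Generate a dataset on disk: train/val/test directories plus a manifest.

    The manifest records the seed, the full configuration, the split
    membership, and a SHA-256 digest per file; re-running with the same
    configuration reproduces byte-identical files.
    """
    out_dir = Path(out_dir)
    splits = simulate_records(cfg, fractions)
    manifest = {
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "fractions": list(fractions),
        "splits": {},
        "digests": {},
    }
    for split, recs in splits.items():
        sdir = out_dir / split
        manifest["splits"][split] = [r.protein_id for r in recs]
        for rec in recs:
            for p in write_record(rec, sdir):
                digest = hashlib.sha256(p.read_bytes()).hexdigest()
                manifest["digests"][f"{split}/{p.name}"] = digest
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _config_dict(cfg: GeneratorConfig) -> dict:
    d = asdict(cfg)
    d["length_range"] = list(cfg.length_range)
    for key in ("phi_dist", "psi_dist"):
        d[key] = {k: [list(c) for c in v] for k, v in d[key].items()}
    return d
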