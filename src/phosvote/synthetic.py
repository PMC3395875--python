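"""Synthetic site universes and correlated binary element-predictor calls.

The real element predictors behind a phosphorylation-site meta-predictor
are external programs; to exercise the voting, search and evaluation
machinery end-to-end this module simulates their binary calls with
controlled marginal behaviour and controlled redundancy:

* each predictor j has target sensitivity Sn_j and specificity Sp_j — on a
  positive site it calls 1 with probability Sn_j, on a negative site with
  probability 1 − Sp_j;
* cross-predictor dependence comes from a one-factor Gaussian copula: a
  shared standard-normal site factor with loading sqrt(rho) is mixed into
  each predictor's latent variable before per-predictor thresholding, so
  rho = 0 gives conditionally independent calls and larger rho makes the
  ensemble increasingly redundant (the property that limits what voting can
  gain) while leaving every marginal Sn_j/Sp_j exact.

The default scenario fixes 15 predictors whose (Sn, Sp) targets span the
spread observed among real phosphorylation-site predictors benchmarked on
plant data — from high-sensitivity/low-specificity callers (Sn 0.96/Sp
0.14) to conservative high-specificity ones (Sn 0.13/Sp 0.97) — on 2000
class-balanced sites with moderate redundancy (rho = 0.3) and a fixed seed.

A companion generator plants phospho-sites in random protein sequences to
exercise the dataset-construction path (FASTA + annotation table).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dataset_io import AMINO_ACIDS, PHOSPHO_RESIDUES, ProteinRecord
from .voting import PredictionMatrix

__all__ = [
    "EnsembleSpec",
    "ProteomeSpec",
    "DEFAULT_SN_SP",
    "DEFAULT_SCENARIO_SEED",
    "simulate_labels",
    "simulate_calls",
    "simulate_ensemble",
    "default_ensemble_spec",
    "default_scenario",
    "simulate_proteome",
]

# (Sn, Sp) targets spanning the observed spread of real element predictors:
# permissive high-Sn callers through conservative high-Sp ones.
DEFAULT_SN_SP: tuple[tuple[float, float], ...] = (
    (0.816, 0.512),
    (0.802, 0.574),
    (0.770, 0.623),
    (0.658, 0.737),
    (0.376, 0.896),
    (0.759, 0.548),
    (0.381, 0.866),
    (0.128, 0.965),
    (0.955, 0.137),
    (0.806, 0.591),
    (0.439, 0.866),
    (0.417, 0.875),
    (0.759, 0.466),
    (0.170, 0.879),
    (0.707, 0.599),
)

DEFAULT_SCENARIO_SEED = 20120203


@dataclass(frozen=True)
class EnsembleSpec:
    """Design of a simulated predictor ensemble."""

    n_sites: int = 2000
    positive_fraction: float = 0.5
    sn: tuple[float, ...] = tuple(s for s, _ in DEFAULT_SN_SP)
    sp: tuple[float, ...] = tuple(p for _, p in DEFAULT_SN_SP)
    rho: float = 0.3
    seed: int = DEFAULT_SCENARIO_SEED

    def __post_init__(self) -> None:
        if self.n_sites < 10:
            raise ValueError("n_sites must be >= 10")
        if not 0.0 < self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in (0, 1]")
        if len(self.sn) != len(self.sp) or not self.sn:
            raise ValueError("sn and sp must be equal-length and non-empty")
        for r in (*self.sn, *self.sp):
            if not 0.0 < r <= 1.0:
                raise ValueError(f"rates must be in (0, 1], got {r}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        object.__setattr__(self, "sn", tuple(float(s) for s in self.sn))
        object.__setattr__(self, "sp", tuple(float(p) for p in self.sp))

    @property
    def n_predictors(self) -> int:
        return len(self.sn)

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return tuple(f"ep{j + 1:02d}" for j in range(self.n_predictors))

    def as_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "positive_fraction": self.positive_fraction,
            "sn": list(self.sn),
            "sp": list(self.sp),
            "rho": self.rho,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleSpec":
        return cls(n_sites=int(d["n_sites"]),
                   positive_fraction=float(d["positive_fraction"]),
                   sn=tuple(d["sn"]), sp=tuple(d["sp"]),
                   rho=float(d["rho"]), seed=int(d["seed"]))


def simulate_labels(spec: EnsembleSpec) -> np.ndarray:
    """Independent Bernoulli(positive_fraction) labels, seeded."""
    rng = np.random.default_rng(spec.seed)
    return (rng.random(spec.n_sites) < spec.positive_fraction).astype(np.int8)


def simulate_calls(labels, spec: EnsembleSpec) -> PredictionMatrix:
    """Correlated binary calls with exact marginal Sn/Sp per predictor.

    Latent variable of predictor j on site i:
    z_ij = sqrt(rho) * f_i + sqrt(1-rho) * e_ij with f, e standard normal,
    thresholded so that P(call=1) equals Sn_j on positives and 1-Sp_j on
    negatives. The label RNG stream is consumed first so that labels +
    calls together are reproducible from the one spec seed.
    """
    y = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    rng.random(spec.n_sites)  # skip the label draw to decorrelate streams
    n, m = y.size, spec.n_predictors
    factor = rng.standard_normal(n)
    eps = rng.standard_normal((n, m))
    z = np.sqrt(spec.rho) * factor[:, None] + np.sqrt(1.0 - spec.rho) * eps
    p_call = np.where(
        y[:, None] == 1,
        np.asarray(spec.sn)[None, :],
        1.0 - np.asarray(spec.sp)[None, :],
    )
    with np.errstate(divide="ignore"):
        cut = norm.ppf(p_call)  # p=1 -> +inf -> always called
    calls = (z < cut).astype(np.int8)
    site_ids = tuple(f"site{i + 1:05d}" for i in range(n))
    return PredictionMatrix(site_ids=site_ids, calls=calls,
                            predictor_names=spec.predictor_names)


def simulate_ensemble(spec: EnsembleSpec) -> tuple[PredictionMatrix, np.ndarray]:
    """Labels plus calls from one spec/seed."""
    y = simulate_labels(spec)
    return simulate_calls(y, spec), y


def default_ensemble_spec(seed: int = DEFAULT_SCENARIO_SEED) -> EnsembleSpec:
    return EnsembleSpec(seed=seed)


def default_scenario() -> tuple[PredictionMatrix, np.ndarray]:
    """The fixed benchmark scenario: 15 realistic predictors, n=2000, seeded."""
    return simulate_ensemble(default_ensemble_spec())


# ---------------------------------------------------------------------------
# proteome generator


@dataclass(frozen=True)
class ProteomeSpec:
    """Design of a planted-site synthetic proteome."""

    n_proteins: int = 50
    mean_length: int = 300
    min_length: int = 30
    ser_rate: float = 0.080
    thr_rate: float = 0.055
    tyr_rate: float = 0.030
    positive_site_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.ser_rate, self.thr_rate, self.tyr_rate,
                  self.positive_site_rate):
            if not 0.0 < r < 1.0:
                raise ValueError("rates must be in (0, 1)")
        if self.ser_rate + self.thr_rate + self.tyr_rate >= 1.0:
            raise ValueError("S/T/Y rates must sum below 1")
        if self.n_proteins < 1 or self.min_length < 25:
            raise ValueError("need n_proteins >= 1 and min_length >= 25")


def simulate_proteome(spec: ProteomeSpec) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Random proteins with planted phospho-sites.

    Residues are drawn i.i.d. with the specified S/T/Y rates (the remaining
    probability mass spread uniformly over the other 17 amino acids); each
    S/T/Y position is independently planted as a positive phospho-site with
    ``positive_site_rate``. Returns the protein records and an annotation
    table (protein_id, position, residue, label) of the planted positives,
    both directly consumable by the dataset-construction functions.
    """
    rng = np.random.default_rng(spec.seed)
    others = [a for a in AMINO_ACIDS if a not in PHOSPHO_RESIDUES]
    residues = list(PHOSPHO_RESIDUES) + others
    sty = [spec.ser_rate, spec.thr_rate, spec.tyr_rate]
    rest = (1.0 - sum(sty)) / len(others)
    probs = np.array(sty + [rest] * len(others))

    proteins: list[ProteinRecord] = []
    rows: list[tuple[str, int, str, int]] = []
    for k in range(spec.n_proteins):
        length = max(spec.min_length,
                     int(rng.poisson(spec.mean_length)))
        seq = "".join(rng.choice(residues, size=length, p=probs))
        pid = f"SYN{k + 1:04d}"
        proteins.append(ProteinRecord(id=pid, sequence=seq))
        for i, aa in enumerate(seq, start=1):
            if aa in PHOSPHO_RESIDUES and rng.random() < spec.positive_site_rate:
                rows.append((pid, i, aa, 1))
    annotations = pd.DataFrame(rows,
                               columns=["protein_id", "position", "residue",
                                        "label"])
    return proteins, annotations
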