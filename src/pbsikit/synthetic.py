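"""Synthetic cohorts and expression matrices with known ground truth.

The generator produces subject-by-region volume profiles from an explicit
linear model plus site (batch) effects and subject-level deviations, so that
every downstream estimate (harmonization, similarity scores, brain-age
models, expression associations) can be checked against planted parameters.

The generative equation for subject ``s`` and region ``r`` is::

    volume[s, r] = mu[r]
                 + beta_age[r] * age[s]
                 + beta_sex[r] * sex[s]
                 + beta_tiv[r] * tiv[s]
                 + shift[site(s), r]
                 + scale[site(s), r] * eps[s, r]

with ``eps[s, r] ~ Normal(0, sd[s]^2)`` and
``sd[s] = het_sd(group(s)) + het_age_slope * (age[s] - age_min)``.

Subject-level deviations are Gaussian; the true distributional form of
inter-subject heterogeneity in real cohorts is unknown, so this is an
explicit modelling assumption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .pbsi import ProfileMatrix

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "ExpressionSpec",
    "generate_cohort",
    "generate_expression",
    "region_labels",
    "write_cohort",
]

PHENOTYPE_COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "site",
    "tiv",
    "dx",
    "fiq",
    "adi_rrb",
    "adi_soc",
    "adi_ver",
)


def region_labels(n_regions: int) -> list[str]:
    """Hemisphere-tagged labels ``L_1..L_h, R_1..R_h`` for an even region count."""
    if n_regions <= 0 or n_regions % 2:
        raise ValueError(f"n_regions must be a positive even integer, got {n_regions}")
    half = n_regions // 2
    return [f"L_{i}" for i in range(1, half + 1)] + [f"R_{i}" for i in range(1, half + 1)]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the cohort generator.

    ``beta_age``, ``beta_sex`` and ``beta_tiv`` may be scalars (shared across
    regions) or vectors of length ``n_regions``.
    """

    n_per_group: int
    n_regions: int = 360
    n_sites: int = 4
    age_range: tuple[float, float] = (6.0, 20.0)
    site_shift_sd: float = 2.0
    site_scale_sd: float = 0.1
    beta_age: float | Sequence[float] = -0.8
    beta_sex: float | Sequence[float] = 3.0
    beta_tiv: float | Sequence[float] = 0.02
    het_sd_nc: float = 4.0
    het_sd_asd: float = 6.0
    het_age_slope: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group <= 0:
            raise ValueError(f"n_per_group must be positive, got {self.n_per_group}")
        if self.n_regions <= 0 or self.n_regions % 2:
            raise ValueError(
                f"n_regions must be a positive even integer, got {self.n_regions}"
            )
        if self.n_sites <= 0:
            raise ValueError(f"n_sites must be positive, got {self.n_sites}")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"age_range must satisfy min < max, got {self.age_range}")
        for name in ("site_shift_sd", "site_scale_sd", "het_sd_nc", "het_sd_asd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SyntheticCohort:
    """Profiles + phenotypes + the planted-effect record.

    ``truth`` holds every random draw of the generative model so the profile
    matrix can be reconstructed exactly (see :func:`reconstruct_profiles`).
    """

    profiles: ProfileMatrix
    phenotypes: pd.DataFrame
    truth: dict = field(repr=False)

    def reconstruct_profiles(self) -> np.ndarray:
        """Rebuild the profile values from ``truth`` via the generative equation."""
        t = self.truth
        mu = np.asarray(t["mu"])
        beta_age = np.asarray(t["beta_age"])
        beta_sex = np.asarray(t["beta_sex"])
        beta_tiv = np.asarray(t["beta_tiv"])
        shift = np.asarray(t["site_shift"])
        scale = np.asarray(t["site_scale"])
        eps = np.asarray(t["eps"])
        ph = self.phenotypes
        age = ph["age"].to_numpy()
        sex = ph["sex"].to_numpy(dtype=float)
        tiv = ph["tiv"].to_numpy()
        site = ph["site"].to_numpy()
        signal = (
            mu[None, :]
            + beta_age[None, :] * age[:, None]
            + beta_sex[None, :] * sex[:, None]
            + beta_tiv[None, :] * tiv[:, None]
        )
        return signal + shift[site] + scale[site] * eps


def _as_region_vector(value, n_regions: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        return np.full(n_regions, arr.item())
    if arr.size != n_regions:
        raise ValueError(f"{name} must be scalar or length {n_regions}, got {arr.size}")
    return arr


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a two-group (ASD/NC) multi-site cohort from ``spec``.

    The same ``(spec, seed)`` reproduces an identical cohort bit-for-bit.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_group
    R = spec.n_regions

    dx = np.array(["ASD"] * spec.n_per_group + ["NC"] * spec.n_per_group)
    age_min, age_max = spec.age_range
    age = rng.uniform(age_min, age_max, size=n)
    sex = rng.integers(0, 2, size=n)
    # log-normal TIV around a nominal 1500 cm^3 mean
    tiv = np.exp(rng.normal(np.log(1500.0), 0.08, size=n))
    # balanced deterministic site assignment, then shuffled
    site = rng.permutation(np.resize(np.arange(spec.n_sites), n))

    mu = 100.0 + 20.0 * rng.standard_normal(R)
    beta_age = _as_region_vector(spec.beta_age, R, "beta_age")
    beta_sex = _as_region_vector(spec.beta_sex, R, "beta_sex")
    beta_tiv = _as_region_vector(spec.beta_tiv, R, "beta_tiv")

    shift = rng.normal(0.0, spec.site_shift_sd, size=(spec.n_sites, R)) \
        if spec.site_shift_sd > 0 else np.zeros((spec.n_sites, R))
    scale = np.exp(rng.normal(0.0, spec.site_scale_sd, size=(spec.n_sites, R))) \
        if spec.site_scale_sd > 0 else np.ones((spec.n_sites, R))

    het_sd = np.where(dx == "ASD", spec.het_sd_asd, spec.het_sd_nc)
    sd = het_sd + spec.het_age_slope * (age - age_min)
    eps = sd[:, None] * rng.standard_normal((n, R))

    signal = (
        mu[None, :]
        + beta_age[None, :] * age[:, None]
        + beta_sex[None, :] * sex[:, None]
        + beta_tiv[None, :] * tiv[:, None]
    )
    values = signal + shift[site] + scale[site] * eps

    # cognition scores: FIQ for everyone, ADI-R subscores only for ASD
    fiq = rng.normal(108.0, 15.0, size=n)
    adi = rng.normal(20.0, 5.0, size=(n, 3))
    adi[dx == "NC"] = np.nan

    subject_ids = [f"S{i:04d}" for i in range(n)]
    phenotypes = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age": age,
            "sex": sex,
            "site": site,
            "tiv": tiv,
            "dx": dx,
            "fiq": fiq,
            "adi_rrb": adi[:, 0],
            "adi_soc": adi[:, 1],
            "adi_ver": adi[:, 2],
        }
    )

    profiles = ProfileMatrix(values=values, subject_ids=subject_ids,
                             region_labels=region_labels(R))
    truth = {
        "spec": asdict(spec),
        "mu": mu,
        "beta_age": beta_age,
        "beta_sex": beta_sex,
        "beta_tiv": beta_tiv,
        "site_shift": shift,
        "site_scale": scale,
        "eps": eps,
        "eps_sd": sd,
        "het_sd_nc": spec.het_sd_nc,
        "het_sd_asd": spec.het_sd_asd,
        "age_min": age_min,
    }
    return SyntheticCohort(profiles=profiles, phenotypes=phenotypes, truth=truth)


@dataclass(frozen=True)
class ExpressionSpec:
    """Parameters of the synthetic gene-by-region expression generator.

    ``noise_sd`` of ``None`` auto-calibrates the independent noise component
    so planted genes have expected absolute Spearman correlation
    ``rho_target`` with the target map (Gaussian-copula calibration);
    an explicit value is used as given.
    """

    n_genes: int
    n_planted: int
    rho_target: float = 0.6
    noise_sd: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not 0 <= self.n_planted <= self.n_genes:
            raise ValueError("n_planted must satisfy 0 <= n_planted <= n_genes")
        if not 0 < self.rho_target <= 1:
            raise ValueError("rho_target must be in (0, 1]")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_expression(
    spec: ExpressionSpec, delta_map: np.ndarray | pd.Series
) -> tuple[pd.DataFrame, list[str]]:
    """Gene-by-region expression with a planted subset tracking ``delta_map``.

    Planted genes are noisy monotone transforms of the delta map; the rest are
    exchangeable Gaussian noise. Returns ``(expression, planted_gene_ids)``
    where ``expression`` is a genes x regions DataFrame whose columns are the
    delta map's region labels.
    """
    spec.validate()
    if isinstance(delta_map, pd.Series):
        labels = list(delta_map.index.astype(str))
        delta = delta_map.to_numpy(dtype=float)
    else:
        delta = np.asarray(delta_map, dtype=float)
        labels = region_labels(delta.size) if delta.size % 2 == 0 else [
            f"R{i}" for i in range(delta.size)
        ]
    if np.ptp(delta) == 0:
        raise ValueError("delta_map is constant; no spatial target to plant")

    rng = np.random.default_rng(spec.seed)
    n_regions = delta.size
    # normal scores of the delta ranks: a monotone transform of delta
    ranks = pd.Series(delta).rank(method="average").to_numpy()
    z = ndtri((ranks - 0.5) / n_regions)
    z = (z - z.mean()) / z.std()

    # Pearson correlation reproducing the target Spearman under a Gaussian copula
    r = 2.0 * np.sin(np.pi * spec.rho_target / 6.0)
    noise_sd = np.sqrt(max(0.0, 1.0 - r * r)) if spec.noise_sd is None else spec.noise_sd

    values = rng.standard_normal((spec.n_genes, n_regions))
    signs = rng.choice([-1.0, 1.0], size=spec.n_planted)
    values[: spec.n_planted] = (
        signs[:, None] * r * z[None, :]
        + noise_sd * rng.standard_normal((spec.n_planted, n_regions))
    )

    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    expr = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=labels)
    return expr, gene_ids[: spec.n_planted]


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Persist ``profiles.csv``, ``phenotypes.csv`` and ``truth.json``."""
    from .io import write_profiles, write_phenotypes

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "profiles": out / "profiles.csv",
        "phenotypes": out / "phenotypes.csv",
        "truth": out / "truth.json",
    }
    write_profiles(cohort.profiles, paths["profiles"])
    write_phenotypes(cohort.phenotypes, paths["phenotypes"])
    truth_json = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in cohort.truth.items()
    }
    paths["truth"].write_text(json.dumps(truth_json))
    return paths
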