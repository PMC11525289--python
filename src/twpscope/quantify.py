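"""Sample-level statistics: LOD/LOQ, concentrations, distributions, tests.

Detection limits follow the blank-based convention
``LOD = mean_blank + 3*sd_blank`` and ``LOQ = mean_blank + 10*sd_blank``,
floored at the method's operational resolution (one particle per processed
subsample): a counting method cannot report a fraction of a particle, so
with clean blanks both limits sit at one particle.

Concentrations extrapolate replicate particle counts from the subsample
dry mass (grams) to particles per kilogram of dry soil. Group differences
between samples use the Kruskal-Wallis rank sum test with Dunn's post-hoc
pairwise z tests (Holm adjustment by default). A rough per-sample mass is
derived from a parameterized ellipsoid volume model with the particle
thickness taken proportional to its mFD.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .morphometry import ParticleTable

__all__ = [
    "BlankStats",
    "SampleQuant",
    "GroupTestResult",
    "MassEstimate",
    "blank_stats",
    "concentration",
    "cumulative_distributions",
    "compare_groups",
    "dunn_test",
    "estimate_mass",
]


@dataclass
class BlankStats:
    blank_counts: np.ndarray
    mean_blank: float
    sd_blank: float
    lod: float  # particles per subsample, floored at the resolution
    loq: float
    operational_resolution: float = 1.0


@dataclass
class SampleQuant:
    sample_id: str
    replicate_counts: np.ndarray
    mass_g: float
    mean_count: float
    concentration_per_kg: float
    se_per_kg: float
    above_lod: bool | None = None


@dataclass
class GroupTestResult:
    h_statistic: float
    df: int
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_unadjusted, p_adjusted
    adjustment: str = "holm"


@dataclass
class MassEstimate:
    total_mass_mg: float
    mass_mg_per_kg: float | None
    model: str
    thickness_k: float
    density_g_cm3: float
    n_particles: int


def blank_stats(
    blank_counts, operational_resolution: float = 1.0
) -> BlankStats:
    """LOD/LOQ from procedural blank counts, floored at the resolution.

    Sample standard deviation (n-1 denominator); a single blank has sd 0.
    """
    counts = np.asarray(blank_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("need at least one blank count")
    if (counts < 0).any():
        raise ValueError("blank counts must be >= 0")
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if counts.size > 1 else 0.0
    lod = max(mean + 3 * sd, operational_resolution)
    loq = max(mean + 10 * sd, operational_resolution)
    return BlankStats(counts, mean, sd, lod, loq, operational_resolution)


def concentration(
    replicate_counts, mass_g: float, sample_id: str = "", lod: float | None = None
) -> SampleQuant:
    """Particles per kg dry soil from replicate counts and subsample mass.

    concentration = mean(counts) * 1000 / mass_g; the standard error scales
    the SD of the replicate counts the same way (NaN for one replicate).
    """
    if mass_g <= 0:
        raise ValueError("subsample mass must be > 0 g")
    counts = np.asarray(replicate_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be >= 0")
    mean = float(counts.mean())
    scale = 1000.0 / mass_g
    if counts.size > 1:
        se = float(counts.std(ddof=1) / np.sqrt(counts.size) * scale)
    else:
        se = float("nan")
    return SampleQuant(
        sample_id=sample_id,
        replicate_counts=counts,
        mass_g=float(mass_g),
        mean_count=mean,
        concentration_per_kg=mean * scale,
        se_per_kg=se,
        above_lod=None if lod is None else bool(mean >= lod),
    )


def _ecdf(values: np.ndarray) -> pd.DataFrame:
    v = np.sort(np.asarray(values, dtype=float))
    uniq, counts = np.unique(v, return_counts=True)
    cum = np.cumsum(counts) / v.size
    return pd.DataFrame({"value": uniq, "cumulative_frequency": cum})


def cumulative_distributions(
    table: ParticleTable | pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Empirical CDFs of FD (µm) and circularity for one particle table.

    Ties collapse into a single step (the plateau carries the full tied
    mass); each CDF is nondecreasing and ends at 1.
    """
    df = table.to_dataframe() if isinstance(table, ParticleTable) else table
    if df.empty:
        warnings.warn("empty particle table: empty cumulative distributions")
        empty = pd.DataFrame({"value": [], "cumulative_frequency": []})
        return {"fd_um": empty, "circularity": empty.copy()}
    return {
        "fd_um": _ecdf(df["fd_um"].to_numpy()),
        "circularity": _ecdf(df["circularity"].to_numpy()),
    }


def dunn_test(
    groups: dict[str, np.ndarray], adjustment: str = "holm"
) -> pd.DataFrame:
    """Dunn's post-hoc pairwise z tests on pooled ranks, tie-corrected.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)),
    with the tie term T = sum(t^3 - t) / (12 (N - 1)); two-sided normal
    p-values, adjusted with the named method over all pairs.
    """
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(data)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g, arr in zip(names, data):
        mean_ranks[g] = float(ranks[start : start + arr.size].mean())
        sizes[g] = arr.size
        start += arr.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    rows = []
    for a, b in itertools.combinations(names, 2):
        denom = np.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term)
            * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        if denom == 0.0:  # every pooled observation identical
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / denom
            p = 2.0 * stats.norm.sf(abs(z))
        rows.append((a, b, float(z), float(p)))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_unadjusted"])
    df["p_adjusted"] = multipletests(df["p_unadjusted"], method=adjustment)[1]
    return df


def compare_groups(
    counts_by_group: dict[str, np.ndarray], adjustment: str = "holm"
) -> GroupTestResult:
    """Kruskal-Wallis across groups, then Dunn pairwise post-hoc tests."""
    if len(counts_by_group) < 2:
        raise ValueError("need at least two groups")
    for g, v in counts_by_group.items():
        if np.asarray(v).size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    arrays = [np.asarray(v, dtype=float) for v in counts_by_group.values()]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):  # degenerate: every observation identical
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    pairwise = dunn_test(
        {g: np.asarray(v, dtype=float) for g, v in counts_by_group.items()},
        adjustment=adjustment,
    )
    return GroupTestResult(
        h_statistic=float(h),
        df=len(counts_by_group) - 1,
        p_value=float(p),
        pairwise=pairwise,
        adjustment=adjustment,
    )


def estimate_mass(
    table: ParticleTable | pd.DataFrame,
    density_g_cm3: float = 1.8,
    thickness_model: str = "ellipsoid",
    thickness_k: float = 0.4,
    subsample_mass_g: float | None = None,
) -> MassEstimate:
    """Parameterized ellipsoid mass estimate for a particle table.

    Per-particle volume = (pi/6) * FD * mFD * (k * mFD) in µm³, thickness
    modelled as k times the mFD; mass = volume * density, reported in mg
    (and mg per kg dry soil when a subsample mass is given). The model tag
    and parameters travel with the result — these are order-of-magnitude
    estimates, not measured masses.
    """
    if density_g_cm3 <= 0:
        raise ValueError("density must be > 0")
    if thickness_model != "ellipsoid":
        raise ValueError(f"unknown thickness model: {thickness_model!r}")
    df = table.to_dataframe() if isinstance(table, ParticleTable) else table
    if df.empty:
        total_mg = 0.0
        n = 0
    else:
        vol_um3 = (
            np.pi / 6.0
            * df["fd_um"].to_numpy()
            * df["mfd_um"].to_numpy()
            * (thickness_k * df["mfd_um"].to_numpy())
        )
        # 1 µm³ = 1e-12 cm³ ; g -> mg is *1e3
        total_mg = float(np.sum(vol_um3) * density_g_cm3 * 1e-12 * 1e3)
        n = len(df)
    per_kg = (
        total_mg * 1000.0 / subsample_mass_g if subsample_mass_g else None
    )
    return MassEstimate(
        total_mass_mg=total_mg,
        mass_mg_per_kg=per_kg,
        model=f"ellipsoid(k={thickness_k})",
        thickness_k=thickness_k,
        density_g_cm3=density_g_cm3,
        n_particles=n,
    )
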