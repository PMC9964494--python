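"""Synthetic two-group cohorts of weighted connectomes.

No imaging data accompany the analysis this package implements, so testing it
end-to-end needs a generator that reproduces the *statistical shape* the
pipeline assumes: 116-node connected networks with modular small-world
topology, heavy-tailed integer streamline-count weights, and a patient group
whose global efficiency is shifted upward (and clustering/path length
downward) by roughly half a pooled standard deviation, alongside demographic
covariates matching a typical case-control panic-disorder sample.

The generative family is a modular (stochastic-block-style) random graph:
nodes are split into ``n_modules`` blocks, edges appear with probability
``p_within`` inside a block and ``p_between`` across blocks, and weights are
integer-rounded log-normals.  The patient effect acts on edge *weights*, not
topology: inter-module weights are multiplied by ``effect_between`` (> 1
raises global efficiency and shortens paths) and intra-module weights by
``effect_within`` (< 1 lowers clustering).  This two-knob scheme reproduces
the direction triple (higher E_glob, lower S_p, lower C_p in patients) that
the analysis is designed to detect.

Determinism: each subject's matrix depends only on the master seed and the
subject's index (a counter-based seed-sequence scheme), so cohorts are
bit-reproducible and subjects can be generated in any order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np

from .io import Cohort, Connectome, SubjectRecord, write_cohort
from .metrics import global_efficiency, shortest_paths

__all__ = [
    "CohortSimConfig",
    "generate_connectome",
    "generate_cohort",
    "calibrate_effect",
    "aal_labels",
]

#: calibrated so the simulated two-group Cohen's d on global efficiency is
#: ~0.5, the magnitude of the anchor study's patient-control contrast
DEFAULT_EFFECT_BETWEEN = 1.115
DEFAULT_EFFECT_WITHIN = 0.90

_MAX_TOPOLOGY_DRAWS = 20


def aal_labels(n: int = 116) -> tuple[str, ...]:
    """Region names in AAL order (90 cerebral + 26 cerebellar/vermis).

    For non-default *n* the list is truncated or padded with synthetic names
    so that small test networks still carry labels.
    """
    base = _AAL_116
    if n <= len(base):
        return tuple(base[:n])
    return tuple(list(base) + [f"Region_{i}" for i in range(len(base) + 1, n + 1)])


@dataclass(frozen=True)
class CohortSimConfig:
    """All knobs of the synthetic cohort.

    Defaults mirror the anchor study's design: 81 patients vs 48 controls,
    116 nodes, covariates drawn from its demographics table, and an effect
    size on global efficiency of about d = 0.5.
    """

    n_pd: int = 81
    n_hc: int = 48
    n_nodes: int = 116
    n_modules: int = 8
    p_within: float = 0.45
    p_between: float = 0.08
    weight_logmean: float = 2.0
    weight_logsd: float = 1.0
    effect_between: float = DEFAULT_EFFECT_BETWEEN
    effect_within: float = DEFAULT_EFFECT_WITHIN
    # covariate distributions (patient group first)
    age_mean_pd: float = 34.09
    age_sd_pd: float = 9.55
    age_mean_hc: float = 36.88
    age_sd_hc: float = 9.82
    male_p_pd: float = 29 / 81
    male_p_hc: float = 14 / 48
    pdss_mean: float = 12.28
    pdss_sd: float = 2.68
    pdss_floor: float = 7.0  # inclusion criterion: PDSS > 7
    hamd_mean_pd: float = 9.0
    hamd_sd_pd: float = 4.0
    hamd_max_pd: float = 17.0  # inclusion criterion: HAMD < 18
    duration_logmedian: float = float(np.log(12.0))  # months
    duration_logsd: float = 1.54
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_within", "p_between", "male_p_pd", "male_p_hc"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.n_pd < 2 or self.n_hc < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.effect_between <= 0 or self.effect_within <= 0:
            raise ValueError("effect multipliers must be positive")
        if self.n_modules < 1 or self.n_modules > self.n_nodes:
            raise ValueError("n_modules must be in [1, n_nodes]")


def _module_assignment(cfg: CohortSimConfig) -> np.ndarray:
    """Nodes split into near-equal contiguous modules."""
    return np.arange(cfg.n_nodes) * cfg.n_modules // cfg.n_nodes


def _subject_rng(cfg: CohortSimConfig, subject_seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, subject_seed]))


def generate_connectome(
    cfg: CohortSimConfig, group: str, subject_seed: int
) -> Connectome:
    """One subject's connectome; deterministic given ``(cfg.seed, subject_seed)``.

    Topology is re-drawn (up to 20 times) until connected; patients get the
    weight multipliers applied before integer rounding.
    """
    if group not in ("PD", "HC"):
        raise ValueError(f"unknown group {group!r}")
    rng = _subject_rng(cfg, subject_seed)
    modules = _module_assignment(cfg)
    same_module = modules[:, None] == modules[None, :]
    iu = np.triu_indices(cfg.n_nodes, k=1)
    labels = aal_labels(cfg.n_nodes)

    for _ in range(_MAX_TOPOLOGY_DRAWS):
        p_edge = np.where(same_module[iu], cfg.p_within, cfg.p_between)
        present = rng.random(len(p_edge)) < p_edge
        raw_w = rng.lognormal(cfg.weight_logmean, cfg.weight_logsd, size=len(p_edge))
        if group == "PD":
            raw_w = raw_w * np.where(
                same_module[iu], cfg.effect_within, cfg.effect_between
            )
        w = np.where(present, np.maximum(np.round(raw_w), 1.0), 0.0)
        W = np.zeros((cfg.n_nodes, cfg.n_nodes))
        W[iu] = w
        W = W + W.T
        c = Connectome(labels=labels, W=W)
        if np.isfinite(shortest_paths(c)).all():
            return c
    raise RuntimeError(
        f"could not draw a connected topology in {_MAX_TOPOLOGY_DRAWS} attempts "
        "(config likely too sparse)"
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    raise RuntimeError("truncated normal rejection sampling failed")


def generate_cohort(
    cfg: CohortSimConfig, out_dir: str | os.PathLike | None = None
) -> Cohort:
    """Full synthetic cohort: connectomes plus demographics and clinical scores.

    Ages are group-specific normals truncated to [18, 60]; gender is Bernoulli
    per group; PDSS (patients only) is normal truncated above the inclusion
    floor; HAMD is a truncated normal for patients and 0 for controls; illness
    duration is log-normal.  With *out_dir* given, matrices, the label list
    and the manifest CSV are written there.
    """
    subjects = []
    for idx in range(cfg.n_pd + cfg.n_hc):
        group = "PD" if idx < cfg.n_pd else "HC"
        conn = generate_connectome(cfg, group, subject_seed=idx)
        rng = _subject_rng(cfg, 10_000 + idx)  # covariate stream, separate from topology
        if group == "PD":
            age = _truncated_normal(rng, cfg.age_mean_pd, cfg.age_sd_pd, 18, 60)
            gender = "M" if rng.random() < cfg.male_p_pd else "F"
            pdss = _truncated_normal(rng, cfg.pdss_mean, cfg.pdss_sd, cfg.pdss_floor + 1e-9, np.inf)
            hamd = round(
                _truncated_normal(rng, cfg.hamd_mean_pd, cfg.hamd_sd_pd, 0, cfg.hamd_max_pd)
            )
            duration = float(
                np.maximum(np.round(rng.lognormal(cfg.duration_logmedian, cfg.duration_logsd)), 1.0)
            )
        else:
            age = _truncated_normal(rng, cfg.age_mean_hc, cfg.age_sd_hc, 18, 60)
            gender = "M" if rng.random() < cfg.male_p_hc else "F"
            pdss = None
            hamd = 0.0
            duration = None
        subjects.append(
            SubjectRecord(
                subject_id=f"{'pd' if group == 'PD' else 'hc'}{idx:03d}",
                group=group,
                age=age,
                gender=gender,
                pdss=pdss,
                hamd=float(hamd),
                duration_months=duration,
                connectome=conn,
            )
        )
    cohort = Cohort(subjects=tuple(subjects))
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def _simulated_cohens_d(
    cfg: CohortSimConfig, effect_between: float, n_per_group: int
) -> float:
    """Cohen's d on global efficiency between simulated PD and HC samples."""
    trial = replace(cfg, effect_between=effect_between)
    e_pd = np.array(
        [
            global_efficiency(shortest_paths(generate_connectome(trial, "PD", 50_000 + i)))
            for i in range(n_per_group)
        ]
    )
    e_hc = np.array(
        [
            global_efficiency(shortest_paths(generate_connectome(trial, "HC", 60_000 + i)))
            for i in range(n_per_group)
        ]
    )
    pooled_sd = np.sqrt((e_pd.var(ddof=1) + e_hc.var(ddof=1)) / 2)
    return float((e_pd.mean() - e_hc.mean()) / pooled_sd)


def calibrate_effect(
    cfg: CohortSimConfig,
    target_d: float,
    n_per_group: int = 200,
    tol: float = 0.1,
    lo: float = 1.0,
    hi: float = 2.0,
    max_iter: int = 20,
) -> float:
    """Bisection on ``effect_between`` until the simulated Cohen's d on global
    efficiency is within *tol* of *target_d*.

    The d is estimated from *n_per_group* simulated subjects per group and is
    monotone increasing in the multiplier, so plain bisection applies; raises
    if [lo, hi] does not bracket the target.
    """
    if target_d < 0:
        raise ValueError("target_d must be >= 0")
    if target_d == 0:
        return 1.0
    d_lo = _simulated_cohens_d(cfg, lo, n_per_group)
    d_hi = _simulated_cohens_d(cfg, hi, n_per_group)
    if not (d_lo <= target_d <= d_hi):
        raise ValueError(
            f"search range [{lo}, {hi}] does not bracket target d={target_d} "
            f"(d({lo})={d_lo:.3f}, d({hi})={d_hi:.3f})"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        d_mid = _simulated_cohens_d(cfg, mid, n_per_group)
        if abs(d_mid - target_d) <= tol:
            return mid
        if d_mid < target_d:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


_AAL_116 = [
    "Precentral_L", "Precentral_R", "Frontal_Sup_L", "Frontal_Sup_R",
    "Frontal_Sup_Orb_L", "Frontal_Sup_Orb_R", "Frontal_Mid_L", "Frontal_Mid_R",
    "Frontal_Mid_Orb_L", "Frontal_Mid_Orb_R", "Frontal_Inf_Oper_L",
    "Frontal_Inf_Oper_R", "Frontal_Inf_Tri_L", "Frontal_Inf_Tri_R",
    "Frontal_Inf_Orb_L", "Frontal_Inf_Orb_R", "Rolandic_Oper_L",
    "Rolandic_Oper_R", "Supp_Motor_Area_L", "Supp_Motor_Area_R",
    "Olfactory_L", "Olfactory_R", "Frontal_Sup_Medial_L", "Frontal_Sup_Medial_R",
    "Frontal_Med_Orb_L", "Frontal_Med_Orb_R", "Rectus_L", "Rectus_R",
    "Insula_L", "Insula_R", "Cingulum_Ant_L", "Cingulum_Ant_R",
    "Cingulum_Mid_L", "Cingulum_Mid_R", "Cingulum_Post_L", "Cingulum_Post_R",
    "Hippocampus_L", "Hippocampus_R", "ParaHippocampal_L", "ParaHippocampal_R",
    "Amygdala_L", "Amygdala_R", "Calcarine_L", "Calcarine_R",
    "Cuneus_L", "Cuneus_R", "Lingual_L", "Lingual_R",
    "Occipital_Sup_L", "Occipital_Sup_R", "Occipital_Mid_L", "Occipital_Mid_R",
    "Occipital_Inf_L", "Occipital_Inf_R", "Fusiform_L", "Fusiform_R",
    "Postcentral_L", "Postcentral_R", "Parietal_Sup_L", "Parietal_Sup_R",
    "Parietal_Inf_L", "Parietal_Inf_R", "SupraMarginal_L", "SupraMarginal_R",
    "Angular_L", "Angular_R", "Precuneus_L", "Precuneus_R",
    "Paracentral_Lobule_L", "Paracentral_Lobule_R", "Caudate_L", "Caudate_R",
    "Putamen_L", "Putamen_R", "Pallidum_L", "Pallidum_R",
    "Thalamus_L", "Thalamus_R", "Heschl_L", "Heschl_R",
    "Temporal_Sup_L", "Temporal_Sup_R", "Temporal_Pole_Sup_L",
    "Temporal_Pole_Sup_R", "Temporal_Mid_L", "Temporal_Mid_R",
    "Temporal_Pole_Mid_L", "Temporal_Pole_Mid_R", "Temporal_Inf_L",
    "Temporal_Inf_R", "Cerebelum_Crus1_L", "Cerebelum_Crus1_R",
    "Cerebelum_Crus2_L", "Cerebelum_Crus2_R", "Cerebelum_3_L", "Cerebelum_3_R",
    "Cerebelum_4_5_L", "Cerebelum_4_5_R", "Cerebelum_6_L", "Cerebelum_6_R",
    "Cerebelum_7b_L", "Cerebelum_7b_R", "Cerebelum_8_L", "Cerebelum_8_R",
    "Cerebelum_9_L", "Cerebelum_9_R", "Cerebelum_10_L", "Cerebelum_10_R",
    "Vermis_1_2", "Vermis_3", "Vermis_4_5", "Vermis_6", "Vermis_7", "Vermis_8",
    "Vermis_9", "Vermis_10",
]
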