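"""ERPs to isolated test duplets and their statistics.

Epochs span [-0.2, 2.0] s around duplet onset (551 samples at 250 Hz);
analysis restricts to [0, 1.5] s (376 time points). Contrasts are tested
two ways: a spatiotemporal cluster-based permutation test (two-sided
clustering threshold alpha 0.10, spatial adjacency <= 2.5 cm, at least 3
electrodes per time slice, cluster mass = summed t, max-mass permutation
null) and per-ROI time-point t-tests BH-FDR corrected over the full
family of 7 ROIs x 376 time points = 2632 tests. A split-plot two-way
ANOVA (duplet type within subject, familiarisation group between) with
generalized eta squared effect sizes guards against effects driven by a
single cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .montage import adjacency as montage_adjacency
from .permutation import fdr_bh
from .preproc import MIN_TEST_TRIALS
from .simeeg import EEGRecording

EPOCH_START_S = -0.2
EPOCH_END_S = 2.0
ANALYSIS_END_S = 1.5
CLUSTER_ALPHA = 0.10
NEIGHBOUR_CM = 2.5
MIN_CLUSTER_ELECTRODES = 3
N_PERM_DEFAULT = 5000


@dataclass
class ERPSet:
    """Per-subject condition-average ERPs.

    ``erps[condition]`` maps to (n_subjects, channels, times) arrays on the
    [-0.2, 2.0] s axis; ``n_trials[condition]`` records clean trial counts.
    """

    erps: dict[str, np.ndarray]
    times_s: np.ndarray
    n_trials: dict[str, int]
    subject_id: str = ""
    group: str = ""
    srate_hz: float = 250.0

    @property
    def meets_trial_criterion(self) -> bool:
        return all(n >= MIN_TEST_TRIALS for n in self.n_trials.values())

    def analysis_window(self) -> np.ndarray:
        return (self.times_s >= 0) & (self.times_s <= ANALYSIS_END_S)


@dataclass
class Cluster:
    electrodes: np.ndarray
    time_indices: np.ndarray
    polarity: int
    mass: float
    p: float
    members: np.ndarray = None  # type: ignore[assignment]  # (k, 2) (elec, time)


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_map: np.ndarray
    times_s: np.ndarray
    params: dict

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p <= alpha]


@dataclass
class ROIResult:
    t: dict[str, np.ndarray]  # per ROI time course of t values
    p: dict[str, np.ndarray]
    p_fdr: dict[str, np.ndarray]
    times_s: np.ndarray
    family_size: int


@dataclass
class AnovaResult:
    table: pd.DataFrame  # effect, F, df1, df2, p, eta_g_sq

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


def epoch_and_average(
    recording: EEGRecording,
    test_events: pd.DataFrame | None = None,
    subject_id: str = "",
    group: str = "",
) -> ERPSet:
    """Epoch test items, reject artifact trials, average per condition.

    A trial is rejected if any sample in its epoch is flagged in the
    artifact mask. Retained epochs are average-referenced and normalised
    by the SD across electrodes and time; no baseline subtraction (the
    preprocessing chain ends with normalisation).
    """
    if test_events is None:
        test_events = recording.events
    if "item_type" not in test_events.columns:
        raise ValueError("test events must carry item_type labels")
    srate = recording.srate_hz
    i0 = int(round(EPOCH_START_S * srate))
    i1 = int(round(EPOCH_END_S * srate))
    n_t = i1 - i0 + 1
    times = (np.arange(n_t) + i0) / srate

    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for _, row in test_events.iterrows():
        c = int(round(row["onset"] * srate))
        lo, hi = c + i0, c + i0 + n_t
        if lo < 0 or hi > recording.n_samples:
            continue
        if recording.artifact_mask[:, lo:hi].any():
            continue
        ep = recording.data[:, lo:hi]
        ep = ep - ep.mean(axis=0, keepdims=True)
        sd = ep.std()
        if sd == 0:
            continue
        ep = ep / sd
        key = row["item_type"]
        sums[key] = sums.get(key, 0) + ep
        counts[key] = counts.get(key, 0) + 1
    if not counts or any(v == 0 for v in counts.values()):
        raise ValueError("a condition has zero clean trials")
    erps = {k: (sums[k] / counts[k])[None, ...] for k in sums}
    return ERPSet(erps, times, counts, subject_id, group, srate)


def stack_erps(sets: list[ERPSet], condition: str) -> np.ndarray:
    """(n_subjects, channels, times) stack of one condition's averages."""
    return np.concatenate([s.erps[condition] for s in sets], axis=0)


# ---------------------------------------------------------------------------
# cluster-based permutation


def _t_map(a: np.ndarray, b: np.ndarray | None, paired: bool) -> tuple[np.ndarray, int]:
    if paired:
        d = a - b if b is not None else a
        n = d.shape[0]
        mu = d.mean(axis=0)
        se = d.std(axis=0, ddof=1) / np.sqrt(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, mu / se, 0.0)
        return t, n - 1
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            sp > 0, (a.mean(axis=0) - b.mean(axis=0)) / (sp * np.sqrt(1 / na + 1 / nb)), 0.0
        )
    return t, na + nb - 2


def find_clusters(
    t_map: np.ndarray,
    t_crit: float,
    adj: np.ndarray,
    min_electrodes: int = MIN_CLUSTER_ELECTRODES,
) -> list[tuple[np.ndarray, float, int]]:
    """Connected supra-threshold components of a channels x times t-map.

    Adjacency: spatial neighbours at the same time point, and the same
    channel at consecutive time points; positive and negative excursions
    cluster separately. Time slices at which a cluster has fewer than
    ``min_electrodes`` members are removed iteratively (components are
    re-extracted) until every remaining slice meets the rule.

    Returns (member (k,2) arrays, mass, polarity) triples.
    """
    results = []
    for sign in (1, -1):
        supra = (sign * t_map) > t_crit
        comps = _components(supra, adj)
        comps = _enforce_min_electrodes(comps, supra.shape, adj, min_electrodes)
        for members in comps:
            mass = float(t_map[members[:, 0], members[:, 1]].sum())
            results.append((members, mass, sign))
    return results


def _components(supra: np.ndarray, adj: np.ndarray) -> list[np.ndarray]:
    """BFS connected components over the supra-threshold mask."""
    nch, nt = supra.shape
    labels = -np.ones(supra.shape, dtype=int)
    comps = []
    neigh_lists = [np.flatnonzero(adj[c]) for c in range(nch)]
    for c0, t0 in zip(*np.nonzero(supra)):
        if labels[c0, t0] >= 0:
            continue
        comp_id = len(comps)
        stack = [(c0, t0)]
        labels[c0, t0] = comp_id
        members = []
        while stack:
            c, t = stack.pop()
            members.append((c, t))
            for c2 in neigh_lists[c]:
                if supra[c2, t] and labels[c2, t] < 0:
                    labels[c2, t] = comp_id
                    stack.append((c2, t))
            for t2 in (t - 1, t + 1):
                if 0 <= t2 < nt and supra[c, t2] and labels[c, t2] < 0:
                    labels[c, t2] = comp_id
                    stack.append((c, t2))
        comps.append(np.array(members))
    return comps


def _enforce_min_electrodes(
    comps: list[np.ndarray],
    shape: tuple[int, int],
    adj: np.ndarray,
    min_electrodes: int,
) -> list[np.ndarray]:
    out = []
    for members in comps:
        current = members
        while len(current):
            times, counts = np.unique(current[:, 1], return_counts=True)
            thin = set(times[counts < min_electrodes])
            if not thin:
                out.append(current)
                break
            keep = np.array([m for m in current if m[1] not in thin])
            if len(keep) == 0:
                break
            sub = np.zeros(shape, dtype=bool)
            sub[keep[:, 0], keep[:, 1]] = True
            subcomps = _components(sub, adj)
            if len(subcomps) == 1:
                current = subcomps[0]
            else:
                out.extend(_enforce_min_electrodes(subcomps, shape, adj, min_electrodes))
                break
    return out


def cluster_permutation(
    erps_a: np.ndarray,
    erps_b: np.ndarray,
    positions: np.ndarray,
    times_s: np.ndarray,
    paired: bool = True,
    alpha_cluster: float = CLUSTER_ALPHA,
    neighbour_cm: float = NEIGHBOUR_CM,
    min_electrodes: int = MIN_CLUSTER_ELECTRODES,
    n_perm: int = N_PERM_DEFAULT,
    seed: int | np.random.Generator = 0,
) -> ClusterResult:
    """Spatiotemporal cluster-based permutation contrast of two ERP stacks.

    ``erps_a``/``erps_b``: (n_subjects, channels, times) restricted to the
    analysis window. Paired contrasts permute condition labels within
    subject (sign flips of the difference); unpaired contrasts permute
    group membership. Cluster p-values come from the permutation
    distribution of the maximal |mass| across both polarities.
    """
    if positions is None:
        raise ValueError("channel positions are required for clustering")
    if erps_a.shape[0] < 2 or (erps_b is not None and erps_b.shape[0] < 2):
        raise ValueError("need at least 2 subjects per cell")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    adj = montage_adjacency(positions, neighbour_cm)

    t_obs, df = _t_map(erps_a, erps_b, paired)
    t_crit = stats.t.ppf(1 - alpha_cluster / 2, df)
    observed = find_clusters(t_obs, t_crit, adj, min_electrodes)

    null_max = np.zeros(n_perm)
    if paired:
        d = erps_a - erps_b
        n = d.shape[0]
        for b in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=n)
            t_p, _ = _t_map(d * signs[:, None, None], None, True)
            cl = find_clusters(t_p, t_crit, adj, min_electrodes)
            null_max[b] = max((abs(m) for _, m, _ in cl), default=0.0)
    else:
        pooled = np.concatenate([erps_a, erps_b], axis=0)
        na = erps_a.shape[0]
        ntot = pooled.shape[0]
        for b in range(n_perm):
            idx = rng.permutation(ntot)
            t_p, _ = _t_map(pooled[idx[:na]], pooled[idx[na:]], False)
            cl = find_clusters(t_p, t_crit, adj, min_electrodes)
            null_max[b] = max((abs(m) for _, m, _ in cl), default=0.0)

    clusters = []
    for members, mass, sign in observed:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_perm)
        clusters.append(
            Cluster(
                electrodes=np.unique(members[:, 0]),
                time_indices=np.unique(members[:, 1]),
                polarity=sign,
                mass=mass,
                p=float(p),
                members=members,
            )
        )
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return ClusterResult(
        clusters,
        t_obs,
        times_s,
        {
            "alpha_cluster": alpha_cluster,
            "neighbour_cm": neighbour_cm,
            "min_electrodes": min_electrodes,
            "n_perm": n_perm,
            "paired": paired,
        },
    )


# ---------------------------------------------------------------------------
# ROI tests


def roi_tests(
    erps_a: np.ndarray,
    erps_b: np.ndarray,
    rois: dict[str, np.ndarray],
    times_s: np.ndarray,
    paired: bool = True,
) -> ROIResult:
    """Per-ROI, per-time-point t-tests with BH-FDR over the whole family."""
    t_all, p_all = {}, {}
    mats = []
    for name, chans in rois.items():
        if len(chans) == 0:
            raise ValueError(f"ROI {name!r} is empty")
        a = erps_a[:, chans, :].mean(axis=1)
        b = erps_b[:, chans, :].mean(axis=1)
        if paired:
            t, p = stats.ttest_rel(a, b, axis=0)
        else:
            t, p = stats.ttest_ind(a, b, axis=0)
        t_all[name], p_all[name] = t, p
        mats.append(p)
    p_mat = np.stack(mats)
    p_adj = fdr_bh(p_mat)
    p_fdr = {name: p_adj[i] for i, name in enumerate(rois)}
    return ROIResult(t_all, p_all, p_fdr, times_s, p_mat.size)


# ---------------------------------------------------------------------------
# split-plot ANOVA


def mixed_anova(window_means: pd.DataFrame) -> AnovaResult:
    """Two-way split-plot ANOVA with generalized eta squared.

    ``window_means`` columns: subject, group (between factor, 2 levels),
    condition (within factor, 2 levels), value (one mean per cell).
    Closed-form sums of squares for the one-within one-between design;
    eta_g^2 = SS_effect / (SS_effect + SS_subjects-within-groups +
    SS_within-error).
    """
    df = window_means
    required = {"subject", "group", "condition", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"columns {required} required")
    piv = df.pivot_table(index=["group", "subject"], columns="condition",
                         values="value")
    if piv.isna().any().any():
        raise ValueError("unbalanced design: every subject needs every condition")
    conds = list(piv.columns)
    if len(conds) != 2 or piv.index.get_level_values("group").nunique() != 2:
        raise ValueError("2 x 2 design required")
    y = piv.to_numpy()  # subjects x 2 conditions
    groups = piv.index.get_level_values("group").to_numpy()
    glabels = pd.unique(groups)
    n_total = y.shape[0]
    grand = y.mean()

    subj_means = y.mean(axis=1)
    cond_means = y.mean(axis=0)
    ss_cond = 0.0
    ss_group = 0.0
    ss_subj_within = 0.0
    ss_inter = 0.0
    for g in glabels:
        sel = groups == g
        ng = sel.sum()
        gm = y[sel].mean()
        ss_group += 2 * ng * (gm - grand) ** 2
        ss_subj_within += 2 * ((subj_means[sel] - gm) ** 2).sum()
        for j in range(2):
            cellm = y[sel, j].mean()
            ss_inter += ng * (cellm - gm - cond_means[j] + grand) ** 2
    ss_cond = n_total * ((cond_means - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err_within = ss_total - ss_group - ss_subj_within - ss_cond - ss_inter

    df_group = 1
    df_subj = n_total - 2
    df_cond = 1
    df_err = n_total - 2

    ms = lambda ss, d: ss / d
    f_group = ms(ss_group, df_group) / ms(ss_subj_within, df_subj)
    f_cond = ms(ss_cond, df_cond) / ms(ss_err_within, df_err)
    f_inter = ms(ss_inter, df_cond) / ms(ss_err_within, df_err)

    denom = ss_subj_within + ss_err_within
    rows = [
        ("group", f_group, df_group, df_subj, ss_group),
        ("condition", f_cond, df_cond, df_err, ss_cond),
        ("interaction", f_inter, df_cond, df_err, ss_inter),
    ]
    table = pd.DataFrame(
        [
            {
                "effect": name,
                "F": F,
                "df1": d1,
                "df2": d2,
                "p": float(stats.f.sf(F, d1, d2)),
                "eta_g_sq": ss / (ss + denom),
            }
            for name, F, d1, d2, ss in rows
        ]
    )
    return AnovaResult(table)
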