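"""End-to-end orchestration of the two-experiment design.

``run_pipeline`` simulates (or loads) one cohort per familiarisation
group — phoneme-structured and voice-structured — through the full
protocol: 120 s random stream, 120 s structured stream, ten 30 s
structured streams each followed by an 18-item test block. It then runs
preprocessing, per-condition entrainment statistics, the sliding-window
learning time course with mixed models, the ERP contrasts, and the adult
rating analysis, writing tidy CSV/JSON results and a run manifest.

Every stage is deterministic given the config seeds; per-subject seeds
are spawned from the cohort seed.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, entrain, erp, io, montage, preproc, simeeg, streamgen, timecourse

log = logging.getLogger("slentrain")

RANDOM_S = 120.0
STRUCTURED_LONG_S = 120.0
SHORT_S = 30.0
N_SHORT = 10


@dataclass
class ExperimentConfig:
    """Protocol, simulation and statistics settings for one full run.

    Defaults follow the study protocol: 120 s random and long structured
    streams, ten 30 s short streams with 18-item test blocks (SOA
    2-2.3 s), 250 Hz, 128 channels.
    """

    groups: tuple[str, ...] = ("phoneme", "voice")
    list_id: str = "A"
    n_subjects_per_group: int = 8
    n_channels: int = 128
    srate_hz: float = 250.0
    n_perm: int = 500
    artifact_rate_per_min: float = 2.0
    seed: int = 0
    sim: dict = field(default_factory=dict)  # overrides for SimulationConfig
    out_dir: str = "slentrain_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "groups" in obj:
            obj["groups"] = tuple(obj["groups"])
        return cls(**obj)


def make_subject_config(cfg: ExperimentConfig, seed: int) -> simeeg.SimulationConfig:
    kwargs = dict(
        n_channels=cfg.n_channels,
        srate_hz=cfg.srate_hz,
        artifact_rate_per_min=cfg.artifact_rate_per_min,
        seed=seed,
    )
    kwargs.update(cfg.sim)
    return simeeg.SimulationConfig(**kwargs)


def simulate_subject(
    group: str, cfg: ExperimentConfig, seed: int
) -> tuple[simeeg.EEGRecording, simeeg.EEGRecording]:
    """One subject's familiarisation recording and test-phase recording."""
    rng = np.random.default_rng(seed)
    scfg = make_subject_config(cfg, seed)
    lex = streamgen.build_lexicon(group, cfg.list_id)

    n_rand = int(RANDOM_S / streamgen.SYLLABLE_S)
    n_long = int(STRUCTURED_LONG_S / streamgen.DUPLET_S)
    n_short = int(SHORT_S / streamgen.DUPLET_S)

    pieces = []
    stream_ids = []
    random_stream = streamgen.generate_random_stream(n_rand, rng)
    pieces.append(simeeg.simulate_stream_eeg(random_stream, scfg, rng=rng))
    stream_ids.append("random")
    t_struct = 0.0
    long_stream = streamgen.generate_structured_stream(
        lex, n_long, rng, streamgen.Condition.structured_long
    )
    pieces.append(
        simeeg.simulate_stream_eeg(
            long_stream, scfg, structured_time_offset_s=t_struct, rng=rng
        )
    )
    stream_ids.append("structured_long")
    t_struct += STRUCTURED_LONG_S
    test_blocks = []
    for b in range(N_SHORT):
        short = streamgen.generate_structured_stream(
            lex, n_short, rng, streamgen.Condition.structured_short
        )
        pieces.append(
            simeeg.simulate_stream_eeg(
                short, scfg, structured_time_offset_s=t_struct, rng=rng
            )
        )
        stream_ids.append(f"structured_short_{b:02d}")
        t_struct += SHORT_S
        test_blocks.append(streamgen.make_test_block(lex, rng))

    for rec, sid in zip(pieces, stream_ids):
        rec.events["stream_id"] = sid
    fam = simeeg.concatenate_recordings(pieces)
    fam = simeeg.inject_artifacts(fam, cfg.artifact_rate_per_min, rng)

    test_rec = simeeg.simulate_test_eeg(test_blocks, scfg, rng=rng)
    test_rec = simeeg.inject_artifacts(test_rec, cfg.artifact_rate_per_min, rng)
    return fam, test_rec


@dataclass
class SubjectResult:
    subject_id: str
    group: str
    record: preproc.SubjectRecord
    snr: dict  # condition -> dict(target_hz -> per-electrode SNR)
    snr_neigh: dict
    duplet_epochs: preproc.EpochSet  # filtered+rejected 0.5 s segments, chronological
    erpset: erp.ERPSet | None


def process_subject(
    subject_id: str,
    group: str,
    fam: simeeg.EEGRecording,
    test_rec: simeeg.EEGRecording,
) -> SubjectResult:
    """Preprocess one subject and compute per-condition spectral statistics."""
    fam_f = preproc.bandpass_filter(fam, 0.1, 40.0)
    fam_f = preproc.bandpass_filter(fam_f, 0.2, None)
    segs = preproc.segment_duplets(fam_f)
    segs = preproc.reject_and_interpolate(segs, fam.channel_positions)

    cond_of = np.where(
        segs.conditions == "random", "random", "structured"
    )
    snr, snr_neigh, n_long = {}, {}, {}
    for cond in ("random", "structured"):
        sel = segs.select(np.flatnonzero(cond_of == cond))
        long = preproc.reshape_long_epochs(sel)
        n_long[cond] = long.n_epochs
        if long.n_epochs >= 2:
            long = preproc.reference_and_normalize(long)
            spec = entrain.compute_itc(long, cond)
            snr[cond] = {
                hz: entrain.compute_snr(spec, hz) for hz in (2.0, 4.0)
            }
            snr_neigh[cond] = {
                hz: entrain.neighbour_average_snr(spec, hz) for hz in (2.0, 4.0)
            }

    erpset = None
    n_word = n_pw = 0
    try:
        test_f = preproc.bandpass_filter(test_rec, 0.2, 20.0)
        erpset = erp.epoch_and_average(test_f, subject_id=subject_id, group=group)
        n_word = erpset.n_trials.get("word", 0)
        n_pw = erpset.n_trials.get("partword", 0)
    except ValueError:
        erpset = None

    record = preproc.apply_inclusion_rules(
        subject_id,
        group,
        n_random_long=n_long.get("random", 0),
        n_structured_long=n_long.get("structured", 0),
        n_word_trials=n_word,
        n_partword_trials=n_pw,
    )
    return SubjectResult(subject_id, group, record, snr, snr_neigh, segs, erpset)


def run_pipeline(cfg: ExperimentConfig) -> Path:
    """Run the full synthetic two-experiment analysis; returns the run directory."""
    t_start = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    manifest: dict = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "stages": {},
    }

    subjects: dict[str, list[SubjectResult]] = {}
    positions = None
    for group in cfg.groups:
        subjects[group] = []
        for i in range(cfg.n_subjects_per_group):
            sid = f"{group}_{i:02d}"
            subj_seed = int(rng.integers(2**31 - 1))
            log.info("simulating %s (seed %d)", sid, subj_seed)
            fam, test_rec = simulate_subject(group, cfg, subj_seed)
            positions = fam.channel_positions
            res = process_subject(sid, group, fam, test_rec)
            subjects[group].append(res)
            log.info(
                "  %s: random long=%d structured long=%d word=%d partword=%d",
                sid,
                res.record.n_random_long,
                res.record.n_structured_long,
                res.record.n_word_trials,
                res.record.n_partword_trials,
            )
    manifest["stages"]["simulate"] = {
        g: [s.subject_id for s in subjects[g]] for g in cfg.groups
    }

    # ---- entrainment statistics per group -------------------------------
    entrain_rows = []
    sig_electrodes: dict[tuple[str, str, float], np.ndarray] = {}
    group_diffs: dict[str, np.ndarray] = {}
    for group in cfg.groups:
        inc = [
            s for s in subjects[group] if s.record.included_entrainment and s.snr
        ]
        if len(inc) < 2:
            raise RuntimeError(f"entrainment stage: <2 included subjects in {group}")
        for cond in ("random", "structured"):
            for hz in (2.0, 4.0):
                tgt = np.stack([s.snr[cond][hz] for s in inc])
                nb = np.stack([s.snr_neigh[cond][hz] for s in inc])
                res = entrain.test_target_vs_neighbours(
                    tgt, nb, n_perm=cfg.n_perm, seed=int(rng.integers(2**31 - 1))
                )
                sig_electrodes[(group, cond, hz)] = np.flatnonzero(
                    res.p_fdr <= 0.05
                )
                for e in range(tgt.shape[1]):
                    entrain_rows.append(
                        dict(
                            group=group,
                            condition=cond,
                            freq_hz=hz,
                            electrode=e,
                            snr_mean=float(tgt[:, e].mean()),
                            p=float(res.p[e]),
                            p_fdr=float(res.p_fdr[e]),
                        )
                    )
        diffs = np.stack(
            [s.snr["structured"][2.0] - s.snr["random"][2.0] for s in inc]
        )
        group_diffs[group] = diffs
        entrain.test_structured_vs_random(
            np.stack([s.snr["structured"][2.0] for s in inc]),
            np.stack([s.snr["random"][2.0] for s in inc]),
            n_perm=cfg.n_perm,
            seed=int(rng.integers(2**31 - 1)),
        )
    if len(cfg.groups) == 2:
        inter = entrain.test_interaction(
            group_diffs[cfg.groups[0]],
            group_diffs[cfg.groups[1]],
            n_perm=cfg.n_perm,
            seed=int(rng.integers(2**31 - 1)),
        )
        manifest["stages"]["interaction"] = {
            "n_significant_fdr": int((inter.p_fdr <= 0.05).sum())
        }
    pd.DataFrame(entrain_rows).to_csv(out / "entrainment.csv", index=False)

    # ---- learning time course + LMM -------------------------------------
    tc_frames = []
    for group in cfg.groups:
        electrodes = sig_electrodes.get((group, "structured", 2.0))
        if electrodes is None or electrodes.size == 0:
            # fall back to the strongest-SNR electrodes when nothing survives FDR
            inc = [s for s in subjects[group] if s.record.included_entrainment]
            mean_snr = np.stack([s.snr["structured"][2.0] for s in inc]).mean(0)
            electrodes = np.argsort(mean_snr)[-10:]
        for s in subjects[group]:
            if not s.record.included_entrainment:
                continue
            tc = timecourse.sliding_itc(s.duplet_epochs, electrodes)
            df = tc.to_frame(s.subject_id)
            df["group"] = group
            tc_frames.append(df)
    tc_all = pd.concat(tc_frames, ignore_index=True)
    tc_all.to_csv(out / "timecourse.csv", index=False)

    lmm_out = {}
    long_sel = (tc_all["time_s"] >= RANDOM_S) & (
        tc_all["time_s"] <= RANDOM_S + STRUCTURED_LONG_S
    )
    for group in cfg.groups:
        df = tc_all[(tc_all["group"] == group) & long_sel].copy()
        df["time_s"] = df["time_s"] - RANDOM_S
        lmm_out[group] = timecourse.fit_lmm_single(df).summary_dict()
    if len(cfg.groups) == 2:
        df = tc_all[long_sel].copy()
        df["time_s"] = df["time_s"] - RANDOM_S
        lmm_out["group_model"] = timecourse.fit_lmm_group(
            df, reference_group=cfg.groups[0]
        ).summary_dict()
    io.write_json(lmm_out, out / "lmm.json")

    # ---- ERP contrasts ---------------------------------------------------
    erp_sets = [
        s.erpset
        for g in cfg.groups
        for s in subjects[g]
        if s.erpset is not None and s.record.included_erp
    ]
    cluster_out = {}
    if len(erp_sets) >= 2 and positions is not None:
        # keep the neighbour graph comparable across montage densities: the
        # 2.5 cm criterion assumes 128 channels
        neighbour_cm = erp.NEIGHBOUR_CM * float(np.sqrt(128 / cfg.n_channels))
        win = erp_sets[0].analysis_window()
        times = erp_sets[0].times_s[win]
        words = erp.stack_erps(erp_sets, "word")[:, :, win]
        pws = erp.stack_erps(erp_sets, "partword")[:, :, win]
        cres = erp.cluster_permutation(
            words,
            pws,
            positions,
            times,
            paired=True,
            neighbour_cm=neighbour_cm,
            n_perm=cfg.n_perm,
            seed=int(rng.integers(2**31 - 1)),
        )
        cluster_out["word_vs_partword"] = [
            dict(
                polarity=c.polarity,
                mass=c.mass,
                p=c.p,
                n_electrodes=len(c.electrodes),
                t_start_s=float(times[c.time_indices.min()]),
                t_end_s=float(times[c.time_indices.max()]),
            )
            for c in cres.clusters[:10]
        ]
        rois = montage.default_rois(positions)
        rres = erp.roi_tests(words, pws, rois, times, paired=True)
        roi_rows = [
            dict(
                roi=name,
                time_s=float(times[i]),
                t=float(rres.t[name][i]),
                p=float(rres.p[name][i]),
                p_fdr=float(rres.p_fdr[name][i]),
            )
            for name in rois
            for i in range(len(times))
        ]
        pd.DataFrame(roi_rows).to_csv(out / "roi_tests.csv", index=False)

        # group contrast on (word+partword)/2, unpaired
        by_group = {
            g: [
                s.erpset
                for s in subjects[g]
                if s.erpset is not None and s.record.included_erp
            ]
            for g in cfg.groups
        }
        if all(len(v) >= 2 for v in by_group.values()) and len(cfg.groups) == 2:
            ga = [
                0.5 * (erp.stack_erps(by_group[g], "word") + erp.stack_erps(by_group[g], "partword"))
                for g in cfg.groups
            ]
            gres = erp.cluster_permutation(
                ga[0][:, :, win],
                ga[1][:, :, win],
                positions,
                times,
                paired=False,
                neighbour_cm=neighbour_cm,
                n_perm=cfg.n_perm,
                seed=int(rng.integers(2**31 - 1)),
            )
            cluster_out["group_contrast"] = [
                dict(polarity=c.polarity, mass=c.mass, p=c.p)
                for c in gres.clusters[:10]
            ]
        # window ANOVA on the largest cluster, if any
        if cres.clusters:
            c0 = cres.clusters[0]
            rows = []
            for g in cfg.groups:
                for s in subjects[g]:
                    if s.erpset is None or not s.record.included_erp:
                        continue
                    for cond in ("word", "partword"):
                        v = s.erpset.erps[cond][0][:, win][
                            np.ix_(c0.electrodes, c0.time_indices)
                        ].mean()
                        rows.append(
                            dict(subject=s.subject_id, group=g, condition=cond, value=v)
                        )
            anova = erp.mixed_anova(pd.DataFrame(rows))
            cluster_out["window_anova"] = anova.table.to_dict("records")
    io.write_json(cluster_out, out / "erp_clusters.json")

    # ---- adult behaviour --------------------------------------------------
    ratings = behavior.simulate_ratings(
        word_effect={"phoneme": 0.45, "voice": 0.3},
        n_per_group={"phoneme": 27, "voice": 30},
        seed=int(rng.integers(2**31 - 1)),
    )
    beh = {}
    for g in ("phoneme", "voice"):
        r = behavior.paired_word_test(ratings, g)
        beh[g] = dict(t=r.t, df=r.df, p=r.p, cohens_d=r.cohens_d)
    beh["anova"] = behavior.mixed_anova_ratings(ratings).table.to_dict("records")
    io.write_json(beh, out / "behavior.json")

    # ---- subject inventory + manifest -------------------------------------
    pd.DataFrame(
        [
            dict(
                subject=s.subject_id,
                group=s.group,
                n_random_long=s.record.n_random_long,
                n_structured_long=s.record.n_structured_long,
                n_word_trials=s.record.n_word_trials,
                n_partword_trials=s.record.n_partword_trials,
                included_entrainment=s.record.included_entrainment,
                included_erp=s.record.included_erp,
                reason=s.record.reason,
            )
            for g in cfg.groups
            for s in subjects[g]
        ]
    ).to_csv(out / "subjects.csv", index=False)
    manifest["runtime_s"] = round(time.time() - t_start, 1)
    io.write_json(manifest, out / "manifest.json")
    log.info("pipeline done in %.1f s -> %s", manifest["runtime_s"], out)
    return out
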