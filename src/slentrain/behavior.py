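"""Adult familiarity-rating analysis and its synthetic rating generator.

Adults rate 18 isolated duplets per block (10 blocks) on a 1-6 scale
after familiarisation with either the phoneme- or the voice-structured
stream. Word vs Part-word recognition is tested per group with a paired t
on subject-level means (Cohen's d = mean difference / SD of differences);
a 2 x 2 split-plot ANOVA (duplet type within, familiarisation group
between) with generalized eta squared tests the interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .erp import AnovaResult, mixed_anova

RATING_MIN, RATING_MAX = 1, 6
ITEMS_PER_BLOCK = 18
N_BLOCKS = 10


@dataclass
class TestResult:
    t: float
    df: int
    p: float
    cohens_d: float


def _subject_condition_means(ratings: pd.DataFrame) -> pd.DataFrame:
    required = {"subject", "group", "item_type", "rating"}
    if not required <= set(ratings.columns):
        raise ValueError(f"rating table needs columns {required}")
    return (
        ratings.groupby(["group", "subject", "item_type"])["rating"]
        .mean()
        .reset_index()
    )


def paired_word_test(ratings: pd.DataFrame, group: str) -> TestResult:
    """Paired t-test of Word vs Part-word mean ratings within one group."""
    means = _subject_condition_means(ratings)
    means = means[means["group"] == group]
    piv = means.pivot(index="subject", columns="item_type", values="rating")
    if piv.shape[0] < 2 or piv.isna().any().any():
        raise ValueError("need >= 2 subjects with both condition means")
    d = piv["word"] - piv["partword"]
    if d.std(ddof=1) == 0:
        # degenerate: identical condition differences for every subject
        sign = float(np.sign(d.mean()))
        t = cohens_d = sign * np.inf if d.mean() != 0 else 0.0
        p = 0.0 if d.mean() != 0 else 1.0
        return TestResult(float(t), len(d) - 1, float(p), float(cohens_d))
    t, p = stats.ttest_rel(piv["word"], piv["partword"])
    cohens_d = d.mean() / d.std(ddof=1)
    return TestResult(float(t), len(d) - 1, float(p), float(cohens_d))


def mixed_anova_ratings(ratings: pd.DataFrame) -> AnovaResult:
    """2 x 2 split-plot ANOVA on subject x item-type mean ratings."""
    means = _subject_condition_means(ratings).rename(
        columns={"item_type": "condition", "rating": "value"}
    )
    if means["group"].nunique() != 2:
        raise ValueError("both familiarisation groups required")
    return mixed_anova(means)


def simulate_ratings(
    word_effect: dict[str, float] | float,
    n_per_group: dict[str, int] | int,
    seed: int | np.random.Generator = 0,
    latent_mean: float = 3.5,
    subject_sd: float = 0.7,
    subject_effect_sd: float = 0.8,
    noise_sd: float = 1.4,
) -> pd.DataFrame:
    """Synthetic rating tables from a discretised latent-normal model.

    Each rating is round(latent) clipped to the 1-6 scale, with
    latent = latent_mean + subject offset + effect/2 * (+1 for Words,
    -1 for Part-words) + noise, where the subject's effect is the group
    ``word_effect`` plus a normal deviation of SD ``subject_effect_sd``
    (listeners differ in how much they learn, which is what keeps the
    subject-level Cohen's d moderate despite 90 trials per condition).
    ``word_effect`` may differ per group (dict) to induce an interaction.
    Half the 180 items per subject are Words, as in the test design.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    if not isinstance(word_effect, dict):
        word_effect = {"phoneme": float(word_effect), "voice": float(word_effect)}
    if not isinstance(n_per_group, dict):
        n_per_group = {g: int(n_per_group) for g in word_effect}
    rows = []
    for group, n in n_per_group.items():
        for i in range(n):
            subj = f"{group}_{i:02d}"
            eff = word_effect[group] + rng.normal(0, subject_effect_sd)
            offset = rng.normal(0, subject_sd)
            for block in range(1, N_BLOCKS + 1):
                kinds = ["word"] * (ITEMS_PER_BLOCK // 2) + [
                    "partword"
                ] * (ITEMS_PER_BLOCK // 2)
                rng.shuffle(kinds)
                for kind in kinds:
                    latent = (
                        latent_mean
                        + offset
                        + (eff / 2 if kind == "word" else -eff / 2)
                        + rng.normal(0, noise_sd)
                    )
                    rating = int(np.clip(round(latent), RATING_MIN, RATING_MAX))
                    rows.append(
                        dict(
                            subject=subj,
                            group=group,
                            item_type=kind,
                            rating=rating,
                            block=block,
                        )
                    )
    return pd.DataFrame(rows)
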