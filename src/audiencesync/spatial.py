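"""Seat-proximity and pair-characteristic analyses of pair-level ISCs.

Seats live on an integer grid where adjacent seats within a row and the same
seat on adjacent rows are both 1 unit apart; pair distance is Euclidean.
Following the emotional-contagion hypothesis, synchrony should *fall* with
distance: the Fisher-z pair ISC is correlated with the square root of seat
distance (the sqrt normalizes the right-skewed distance distribution), and
the correlation is tested against a permutation null obtained by shuffling
the ISC values across pairs (10,000 draws by default).

Three p-value conventions are exposed:

* ``directional`` (default): one-sided in the hypothesized direction, e.g.
  p = #{r_perm <= r_obs}/n_perm for the negative proximity hypothesis;
* ``paper_literal``: p = #{r_perm >= r_obs}/n_perm regardless of direction;
* ``add_one``: the directional count with the (k+1)/(n+1) correction.

Pair characteristics follow the published groupings: total (summed) age and
empathy per pair; gender pairs female/female, male/male or different (other
or unknown gender excludes the pair); age pairs young (both < 25), old
(both > 25) or different — a member aged exactly 25 satisfies neither strict
inequality, so any pair containing one is "different".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import BayesSpec, bf_correlation, bic_model_scores
from .isc import effectively_constant
from .recording_io import AudienceRecording, ParticipantInfo

__all__ = [
    "PairFeatures",
    "PermutationResult",
    "seat_distance",
    "proximity_correlation",
    "permutation_test_proximity",
    "pair_features",
    "attach_pair_features",
    "feature_association",
    "group_contrast",
]

logger = logging.getLogger(__name__)

P_RULES = ("directional", "paper_literal", "add_one")


def seat_distance(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Euclidean distance in seat units: sqrt(drow^2 + dseat^2)."""
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


@dataclass(frozen=True)
class PairFeatures:
    """Summed traits and group labels for one unordered pair."""

    total_age: float | None
    total_empathy: float | None
    gender_group: str  # female | male | different | excluded
    age_group: str     # young | old | different


@dataclass(frozen=True)
class PermutationResult:
    observed_r: float
    n_permutations: int
    p: float
    seed: int
    alternative: str
    p_rule: str


def pair_features(info_a: ParticipantInfo, info_b: ParticipantInfo) -> PairFeatures:
    """Compute total age/empathy and gender/age groupings for a pair."""
    total_age = (
        None
        if info_a.age is None or info_b.age is None
        else info_a.age + info_b.age
    )
    total_emp = (
        None
        if info_a.empathy_total is None or info_b.empathy_total is None
        else info_a.empathy_total + info_b.empathy_total
    )
    ga, gb = info_a.gender, info_b.gender
    if "other" in (ga, gb):
        gender_group = "excluded"
    elif ga == gb:
        gender_group = ga
    else:
        gender_group = "different"
    if total_age is None:
        age_group = "different"
    elif info_a.age < 25 and info_b.age < 25:
        age_group = "young"
    elif info_a.age > 25 and info_b.age > 25:
        age_group = "old"
    else:
        age_group = "different"
    return PairFeatures(total_age, total_emp, gender_group, age_group)


def attach_pair_features(
    table: pd.DataFrame, recording: AudienceRecording
) -> pd.DataFrame:
    """Join PairFeatures columns onto a pair-ISC table (by participant ids)."""
    cache: dict[tuple[str, str], PairFeatures] = {}
    cols = {"total_age": [], "total_empathy": [], "gender_group": [],
            "age_group": []}
    for pa, pb in zip(table["participant_a"], table["participant_b"]):
        key = (pa, pb)
        if key not in cache:
            cache[key] = pair_features(recording.info[pa], recording.info[pb])
        f = cache[key]
        cols["total_age"].append(np.nan if f.total_age is None else f.total_age)
        cols["total_empathy"].append(
            np.nan if f.total_empathy is None else f.total_empathy
        )
        cols["gender_group"].append(f.gender_group)
        cols["age_group"].append(f.age_group)
    out = table.copy()
    for k, v in cols.items():
        out[k] = v
    return out


def _proximity_xy(table: pd.DataFrame, expression: str) -> tuple[np.ndarray, np.ndarray]:
    sub = table[table["expression"] == expression]
    ok = sub["z"].notna() & sub["seat_distance"].notna()
    sub = sub[ok]
    return np.sqrt(sub["seat_distance"].to_numpy()), sub["z"].to_numpy()


def proximity_correlation(table: pd.DataFrame, expression: str) -> float:
    """Pearson r between sqrt(seat distance) and Fisher-z ISC across pairs."""
    x, z = _proximity_xy(table, expression)
    if len(x) < 4:
        raise ValueError(f"{expression}: need >= 4 pairs with defined z and distance")
    if effectively_constant(x) or effectively_constant(z):
        warnings.warn(
            f"{expression}: zero variance, proximity correlation undefined",
            stacklevel=2,
        )
        return float("nan")
    return float(np.corrcoef(x, z)[0, 1])


def permutation_test_proximity(
    table: pd.DataFrame,
    expression: str,
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "negative",
    p_rule: str = "directional",
) -> PermutationResult:
    """Permutation test of the proximity-ISC correlation.

    The pair ISC (z) values are shuffled across pairs ``n_perm`` times and
    the correlation with sqrt(distance) recomputed, giving the null
    distribution of r under exchangeability.  See module docstring for the
    p-value conventions.
    """
    if alternative not in ("negative", "positive"):
        raise ValueError("alternative must be 'negative' or 'positive'")
    if p_rule not in P_RULES:
        raise ValueError(f"p_rule must be one of {P_RULES}")
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} is very small", stacklevel=2)
    x, z = _proximity_xy(table, expression)
    r_obs = proximity_correlation(table, expression)
    rng = np.random.default_rng(seed)
    # vectorized: each permutation is a row of shuffled z values
    perms = np.stack([rng.permutation(z) for _ in range(n_perm)])
    xc = (x - x.mean()) / x.std()
    pc = perms - perms.mean(axis=1, keepdims=True)
    r_perm = (pc @ xc) / (np.sqrt((pc ** 2).sum(axis=1)) * np.sqrt(len(x)))

    if p_rule == "paper_literal":
        p = float((r_perm >= r_obs).mean())
    else:
        if alternative == "negative":
            k = int((r_perm <= r_obs).sum())
        else:
            k = int((r_perm >= r_obs).sum())
        p = (k + 1) / (n_perm + 1) if p_rule == "add_one" else k / n_perm
    logger.info(
        "proximity permutation (%s): r_obs=%.4f p=%.4g (rule=%s, alt=%s)",
        expression, r_obs, p, p_rule, alternative,
    )
    return PermutationResult(
        observed_r=r_obs,
        n_permutations=n_perm,
        p=p,
        seed=seed,
        alternative=alternative,
        p_rule=p_rule,
    )


def feature_association(
    table: pd.DataFrame,
    feature: str,
    expression: str,
    spec: BayesSpec = BayesSpec(one_sided_positive=False),
) -> dict:
    """Correlation of a pair trait (total_age / total_empathy) with pair ISC.

    Returns the Pearson r and BF10 for the requested feature plus the
    four-model comparison {null, age, empathy, age+empathy} scored by BIC
    posterior odds over pairs complete on both features.
    """
    if feature not in ("total_age", "total_empathy"):
        raise ValueError("feature must be 'total_age' or 'total_empathy'")
    sub = table[table["expression"] == expression]
    ok = sub["z"].notna() & sub[feature].notna()
    if int(ok.sum()) < 4:
        raise ValueError(f"{expression}: fewer than 4 complete pairs for {feature}")
    f = sub.loc[ok, feature].to_numpy(dtype=float)
    z = sub.loc[ok, "z"].to_numpy()
    if effectively_constant(f) or effectively_constant(z):
        warnings.warn(f"{expression}: constant {feature}", stacklevel=2)
        return {"feature": feature, "expression": expression, "r": np.nan,
                "bf10": np.nan, "n_pairs": int(ok.sum()), "models": None}
    r = float(np.corrcoef(f, z)[0, 1])
    bf = bf_correlation(r, int(ok.sum()), spec).bf10 if abs(r) < 1 else np.inf

    both = sub["z"].notna() & sub["total_age"].notna() & sub["total_empathy"].notna()
    models = None
    if int(both.sum()) >= 6:
        zz = sub.loc[both, "z"].to_numpy()
        age = sub.loc[both, "total_age"].to_numpy(dtype=float)
        emp = sub.loc[both, "total_empathy"].to_numpy(dtype=float)
        nb = len(zz)
        designs = {
            "null": np.ones((nb, 1)),
            "age": np.column_stack([np.ones(nb), age]),
            "empathy": np.column_stack([np.ones(nb), emp]),
            "age+empathy": np.column_stack([np.ones(nb), age, emp]),
        }
        specs = []
        names = []
        for name, Xd in designs.items():
            beta, _, rank, _ = np.linalg.lstsq(Xd, zz, rcond=None)
            resid = zz - Xd @ beta
            specs.append((Xd.shape[1], max(float(resid @ resid), 1e-12)))
            names.append(name)
        scores, ranking = bic_model_scores(specs, nb)
        models = pd.DataFrame(
            {"model": names, "score": scores}
        ).sort_values("score", ascending=False, ignore_index=True)
    return {
        "feature": feature,
        "expression": expression,
        "r": r,
        "bf10": bf,
        "n_pairs": int(ok.sum()),
        "models": models,
    }


def group_contrast(table: pd.DataFrame, expression: str) -> dict:
    """Gender/age group means of pair ISC plus the three-model comparison.

    Cell means of Fisher-z ISC per (gender_group, age_group); gender-excluded
    pairs are dropped.  Models, all containing the age-group main effect as
    in the published analysis: null (age only), +gender, +gender x age —
    scored by BIC posterior odds.  Empty cells are reported, not fabricated.
    """
    sub = table[
        (table["expression"] == expression)
        & (table["gender_group"] != "excluded")
        & table["z"].notna()
    ]
    genders = sorted(sub["gender_group"].unique())
    if len(genders) < 2:
        raise ValueError(f"{expression}: needs >= 2 gender groups, have {genders}")
    means = (
        sub.groupby(["gender_group", "age_group"])["z"]
        .agg(["mean", "count"])
        .reset_index()
    )
    z = sub["z"].to_numpy()
    n = len(z)
    g_dummies = pd.get_dummies(sub["gender_group"], drop_first=True).to_numpy(float)
    a_dummies = pd.get_dummies(sub["age_group"], drop_first=True).to_numpy(float)
    inter = np.column_stack(
        [g_dummies[:, i] * a_dummies[:, j]
         for i in range(g_dummies.shape[1])
         for j in range(a_dummies.shape[1])]
    ) if g_dummies.size and a_dummies.size else np.empty((n, 0))
    designs = {
        "age": np.column_stack([np.ones(n), a_dummies]),
        "age+gender": np.column_stack([np.ones(n), a_dummies, g_dummies]),
        "age+gender+gender:age": np.column_stack(
            [np.ones(n), a_dummies, g_dummies, inter]
        ),
    }
    specs = []
    names = []
    for name, Xd in designs.items():
        rank = np.linalg.matrix_rank(Xd)
        if rank < Xd.shape[1]:  # empty cells make the interaction unidentifiable
            warnings.warn(f"{expression}: model {name} not identifiable; skipped",
                          stacklevel=2)
            continue
        beta, _, _, _ = np.linalg.lstsq(Xd, z, rcond=None)
        resid = z - Xd @ beta
        specs.append((Xd.shape[1], max(float(resid @ resid), 1e-12)))
        names.append(name)
    scores, ranking = bic_model_scores(specs, n)
    models = pd.DataFrame({"model": names, "score": scores}).sort_values(
        "score", ascending=False, ignore_index=True
    )
    return {"expression": expression, "cell_means": means, "models": models}
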