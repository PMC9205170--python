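"""KS-style connectivity scoring of up/down query signatures against rank profiles.

A query signature is a pair of disjoint feature sets (up- and down-regulated
in a phenotype of interest).  Each reference profile is a full ranking of
features for one perturbagen, most up-regulated first.  Scoring follows the
classic connectivity-map build-02 scheme: a signed Kolmogorov-Smirnov
enrichment statistic per tag set, combined into a raw connectivity value that
is positive when the perturbagen mimics the query and negative when it
reverses it, then normalized to +/-100 across the scored collection.
Perturbagens scoring at or below a threshold (the selection rule here is
<= -95) in two independent query results are intersected into a candidate
list of signature-reversing compounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QuerySignature",
    "ReferenceProfile",
    "ConnectivityHit",
    "ks_enrichment",
    "raw_connectivity",
    "score_profiles",
    "connectivity_score",
    "select_candidates",
    "read_profiles",
    "write_profiles",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = -95.0
_MAX_TAG_LOSS = 0.5  # profiles covering < 50% of a tag set are not scored


@dataclass(frozen=True)
class QuerySignature:
    """Disjoint up/down feature sets defining the phenotype to query."""

    up_set: frozenset
    down_set: frozenset

    def __post_init__(self):
        up, down = frozenset(self.up_set), frozenset(self.down_set)
        if up & down:
            raise ValueError("up and down sets must be disjoint")
        if not up or not down:
            raise ValueError("both up and down sets must be non-empty")
        object.__setattr__(self, "up_set", up)
        object.__setattr__(self, "down_set", down)

    def swapped(self) -> "QuerySignature":
        return QuerySignature(self.down_set, self.up_set)

    @classmethod
    def read(cls, up_path, down_path) -> "QuerySignature":
        read = lambda p: frozenset(
            line.strip() for line in open(p) if line.strip()
        )
        return cls(read(up_path), read(down_path))


@dataclass(frozen=True)
class ReferenceProfile:
    """One perturbagen instance: every feature ranked, most up-regulated first."""

    perturbagen_id: str
    ranking: tuple

    def __post_init__(self):
        ranking = tuple(self.ranking)
        if len(set(ranking)) != len(ranking):
            raise ValueError("ranking contains duplicate features")
        object.__setattr__(self, "ranking", ranking)

    def reversed_profile(self) -> "ReferenceProfile":
        return ReferenceProfile(self.perturbagen_id, self.ranking[::-1])


@dataclass(frozen=True)
class ConnectivityHit:
    perturbagen_id: str
    score: float  # in [-100, 100]; negative = reverses the query
    n_instances: int
    score_sd: float  # dispersion across instances, same +/-100 scale


def ks_enrichment(tag_set, profile: ReferenceProfile) -> float:
    """Signed KS statistic for the placement of ``tag_set`` in the ranking.

    Positive when the tags concentrate near the top of the profile, negative
    near the bottom.  With t tags among n features at 1-based positions
    pos_1 < ... < pos_t:

        a = max_j ( j/t - pos_j/n ),  b = max_j ( pos_j/n - (j-1)/t )

    and the statistic is a if a > b else -b.  Tags filling the top t ranks
    give exactly +(1 - t/n); tags at the bottom mirror to the negative.
    """
    tags = set(tag_set)
    if not tags:
        raise ValueError("tag set must be non-empty")
    n = len(profile.ranking)
    pos = np.sort([i + 1 for i, f in enumerate(profile.ranking) if f in tags])
    missing = len(tags) - pos.size
    if missing:
        raise KeyError(f"{missing} tag(s) absent from profile {profile.perturbagen_id}")
    t = pos.size
    j = np.arange(1, t + 1)
    a = np.max(j / t - pos / n)
    b = np.max(pos / n - (j - 1) / t)
    return float(a) if a > b else float(-b)


def _coverage_filtered(tags: frozenset, profile: ReferenceProfile) -> set | None:
    present = tags & set(profile.ranking)
    lost = 1.0 - len(present) / len(tags)
    if lost > _MAX_TAG_LOSS:
        return None
    if present != tags:
        warnings.warn(
            f"{len(tags) - len(present)} query feature(s) absent from "
            f"profile {profile.perturbagen_id}; dropped",
            stacklevel=3,
        )
    return set(present)


def raw_connectivity(query: QuerySignature, profile: ReferenceProfile) -> float:
    """Unnormalized connectivity of one profile: (ks_up - ks_down)/2 when the
    two statistics disagree in sign, else 0 (the null convention)."""
    up = _coverage_filtered(query.up_set, profile)
    down = _coverage_filtered(query.down_set, profile)
    if up is None or down is None:
        raise KeyError(
            f"profile {profile.perturbagen_id} covers < 50% of a query tag set"
        )
    a = ks_enrichment(up, profile)
    b = ks_enrichment(down, profile)
    if np.sign(a) == np.sign(b):
        return 0.0
    return (a - b) / 2.0


def score_profiles(query: QuerySignature, profiles: list[ReferenceProfile]) -> list[ConnectivityHit]:
    """Score a collection; normalize per-perturbagen mean raw values to +/-100.

    Multiple instances of one perturbagen are averaged, with the spread
    reported as score_sd.  Profiles with insufficient tag coverage are
    excluded with a warning.  The perturbagen with the largest |mean raw|
    lands at exactly +100 or -100.
    """
    raw: dict[str, list[float]] = {}
    for profile in profiles:
        try:
            raw.setdefault(profile.perturbagen_id, []).append(raw_connectivity(query, profile))
        except KeyError as err:
            warnings.warn(str(err), stacklevel=2)
            raw.setdefault(profile.perturbagen_id, [])
    means = {p: float(np.mean(v)) for p, v in raw.items() if v}
    if not means:
        return []
    scale = max(abs(m) for m in means.values())
    norm = (lambda v: 100.0 * v / scale) if scale > 0 else (lambda v: 0.0)
    hits = []
    for pid, values in raw.items():
        if not values:
            continue
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        hits.append(
            ConnectivityHit(pid, norm(means[pid]), len(values), norm(sd) if scale > 0 else 0.0)
        )
    return sorted(hits, key=lambda h: (h.score, h.perturbagen_id))


def connectivity_score(query: QuerySignature, profile: ReferenceProfile) -> ConnectivityHit:
    """Score a single profile; with a one-profile collection the
    normalization is by its own |raw|, so the score is -100, 0 or +100."""
    return score_profiles(query, [profile])[0]


def select_candidates(
    hits_a: list[ConnectivityHit],
    hits_b: list[ConnectivityHit],
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Perturbagens at or below ``threshold`` in BOTH hit lists.

    Returns a table (perturbagen_id, score_a, score_b, mean_score) sorted by
    mean score ascending (strongest reversers first), then id.
    """
    if not -100.0 <= threshold <= 0.0:
        raise ValueError("threshold must lie in [-100, 0]")
    a = {h.perturbagen_id: h.score for h in hits_a if h.score <= threshold}
    b = {h.perturbagen_id: h.score for h in hits_b if h.score <= threshold}
    shared = sorted(a.keys() & b.keys())
    rows = [
        {"perturbagen_id": p, "score_a": a[p], "score_b": b[p], "mean_score": (a[p] + b[p]) / 2.0}
        for p in shared
    ]
    df = pd.DataFrame(rows, columns=["perturbagen_id", "score_a", "score_b", "mean_score"])
    return df.sort_values(by=["mean_score", "perturbagen_id"]).reset_index(drop=True)


def read_profiles(path) -> list[ReferenceProfile]:
    """Read a GCT-like TSV: feature_id column + one rank column per perturbagen
    (rank 1 = most up-regulated)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    profiles = []
    for col in df.columns:
        order = df[col].sort_values().index
        profiles.append(ReferenceProfile(str(col), tuple(str(f) for f in order)))
    return profiles


def write_profiles(profiles: list[ReferenceProfile], path) -> None:
    features = sorted({f for p in profiles for f in p.ranking})
    data = {}
    for p in profiles:
        rank = {f: i + 1 for i, f in enumerate(p.ranking)}
        data[p.perturbagen_id] = [rank.get(f, np.nan) for f in features]
    pd.DataFrame(data, index=pd.Index(features, name="feature_id")).to_csv(path, sep="\t")
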