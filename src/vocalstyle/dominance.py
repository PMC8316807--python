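"""Dominance ranks and dominance-style measures.

Implements modified David's scores from decided aggressive bouts, the four
dominance-style measures (aggression symmetry / DII, counteraggression,
aggression intensity, feeding proximity), the given/received partition by
rank, and the cross-species composite dominance-style index.

Conventions
-----------
* Ranks come from modified David's scores computed on decided bouts only
  (winner determined by the victim fleeing or submitting).
* "Given tolerance" restricts an individual's measures to dyads with
  strictly lower-ranking partners; "received tolerance" to strictly
  higher-ranking partners; direction ``all`` applies no restriction (used
  for the species-level composite).  Dyads with exactly tied normalized
  scores are excluded from both restricted directions.
* The composite index averages cross-species z-scores of species-mean DII,
  counteraggression and (negated) aggression intensity, so a larger
  composite always means a more tolerant species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np

from .tables import AggressionBout, GroupMeta, ProximityScan, ValidationError

Direction = Literal["given", "received", "all"]

#: Default minimum bouts backing an individual-level style measure.
DEFAULT_MIN_BOUTS = 10
#: Default minimum decided bouts an individual must appear in to be ranked.
DEFAULT_MIN_DECIDED = 3


# ---------------------------------------------------------------------------
# Win matrix and modified David's scores
# ---------------------------------------------------------------------------

@dataclass
class WinMatrix:
    """Dyadic win/interaction counts from decided bouts.

    ``s[i, j]`` is the number of decided bouts won by individual *i* over
    *j*; ``n = s + s.T`` is the symmetric interaction count.
    """

    individuals: list[str]
    s: np.ndarray
    n: np.ndarray

    def index(self, individual: str) -> int:
        return self.individuals.index(individual)


@dataclass
class RankTable:
    """Modified David's scores, normalized scores and ordinal ranks."""

    individuals: list[str]
    ds: np.ndarray         # sum to 0
    norm_ds: np.ndarray    # in [0, N-1]
    rank: np.ndarray       # permutation of 1..N, 1 = highest norm_ds
    tied: np.ndarray       # flag: norm_ds exactly equal to another individual's

    def norm_of(self, individual: str) -> float:
        return float(self.norm_ds[self.individuals.index(individual)])


def build_win_matrix(bouts: Sequence[AggressionBout],
                     min_decided: int = 0) -> WinMatrix:
    """Tally decided bouts into a win matrix for one group.

    Undecided bouts are ignored.  Individuals appearing in fewer than
    ``min_decided`` decided bouts are dropped (together with their bouts)
    before tallying; the default keeps everyone.
    """
    decided = [b for b in bouts if b.decided]
    if not decided:
        raise ValidationError("rank undeterminable: no decided bouts")
    groups = {b.group_id for b in bouts}
    if len(groups) > 1:
        raise ValidationError(f"bouts span multiple groups: {sorted(groups)}")

    if min_decided > 0:
        counts: dict[str, int] = {}
        for b in decided:
            counts[b.aggressor_id] = counts.get(b.aggressor_id, 0) + 1
            counts[b.victim_id] = counts.get(b.victim_id, 0) + 1
        keep = {i for i, c in counts.items() if c >= min_decided}
        decided = [b for b in decided
                   if b.aggressor_id in keep and b.victim_id in keep]
        if not decided:
            raise ValidationError(
                "rank undeterminable: no decided bouts after min_decided filter")

    individuals = sorted({b.aggressor_id for b in decided}
                         | {b.victim_id for b in decided})
    idx = {ind: k for k, ind in enumerate(individuals)}
    n_ind = len(individuals)
    s = np.zeros((n_ind, n_ind), dtype=float)
    for b in decided:
        loser = b.victim_id if b.winner_id == b.aggressor_id else b.aggressor_id
        s[idx[b.winner_id], idx[loser]] += 1
    return WinMatrix(individuals=individuals, s=s, n=s + s.T)


def modified_davids_score(w: WinMatrix) -> RankTable:
    """Modified David's scores from dyadic win proportions.

    The win proportion P_ij = s_ij / n_ij is shrunk toward 0.5 by the
    interaction-count correction D_ij = P_ij - (P_ij - 0.5) / (n_ij + 1);
    unobserved dyads contribute 0.  DS_i = w1_i + w2_i - l1_i - l2_i with
    w2/l2 the interaction-weighted second-order terms, and
    normDS_i = (DS_i + N(N-1)/2) / N lies in [0, N-1].
    """
    n_ind = len(w.individuals)
    if n_ind < 2:
        raise ValidationError("modified David's score requires N >= 2")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(w.n > 0, w.s / np.where(w.n > 0, w.n, 1.0), 0.0)
    d = np.where(w.n > 0, p - (p - 0.5) / (w.n + 1.0), 0.0)
    w1 = d.sum(axis=1)
    w2 = d @ w1
    l1 = d.sum(axis=0)
    l2 = d.T @ l1
    ds = w1 + w2 - l1 - l2
    norm_ds = (ds + n_ind * (n_ind - 1) / 2.0) / n_ind
    table = RankTable(individuals=list(w.individuals), ds=ds, norm_ds=norm_ds,
                      rank=np.zeros(n_ind, dtype=int),
                      tied=np.zeros(n_ind, dtype=bool))
    return assign_ranks(table)


def assign_ranks(rt: RankTable) -> RankTable:
    """Ordinal ranks by descending normDS; ties broken by identifier order
    (lexicographic) and flagged."""
    order = sorted(range(len(rt.individuals)),
                   key=lambda k: (-rt.norm_ds[k], rt.individuals[k]))
    rank = np.zeros(len(order), dtype=int)
    for pos, k in enumerate(order, start=1):
        rank[k] = pos
    values, counts = np.unique(rt.norm_ds, return_counts=True)
    tied_values = set(values[counts > 1])
    tied = np.array([v in tied_values for v in rt.norm_ds])
    rt.rank = rank
    rt.tied = tied
    return rt


# ---------------------------------------------------------------------------
# Dominance-style measures
# ---------------------------------------------------------------------------

def dyad_dii(bouts_in_dyad: Sequence[AggressionBout]) -> float:
    """Directional inconsistency index of one dyad.

    The proportion of bouts (decided or not) in which the roles of
    aggressor and victim occurred in the least frequent direction:
    min(a, b) / (a + b).  0 means fully asymmetric, 0.5 fully symmetric.
    """
    if not bouts_in_dyad:
        raise ValidationError("dyad_dii: empty input")
    pair = {bouts_in_dyad[0].aggressor_id, bouts_in_dyad[0].victim_id}
    a = b = 0
    first = min(pair)
    for bout in bouts_in_dyad:
        if {bout.aggressor_id, bout.victim_id} != pair:
            raise ValidationError("dyad_dii: bouts from more than one dyad")
        if bout.aggressor_id == first:
            a += 1
        else:
            b += 1
    return min(a, b) / (a + b)


@dataclass
class ToleranceProfile:
    """Per-individual dominance-style measures in one direction.

    Measures are ``None`` (missing) when backed by fewer than the configured
    minimum number of bouts.  ``dii`` is a proportion in [0, 0.5];
    ``counter_pct`` and ``intensity_pct`` are percentages.
    """

    individual_id: str
    direction: Direction
    dii: Optional[float]
    counter_pct: Optional[float]
    intensity_pct: Optional[float]
    n_bouts: int


def tolerance_profile(bouts: Sequence[AggressionBout],
                      ranks: RankTable,
                      direction: Direction,
                      min_bouts: int = DEFAULT_MIN_BOUTS,
                      dii_mode: Literal["pooled", "dyad_mean"] = "pooled",
                      ) -> dict[str, ToleranceProfile]:
    """Tolerance measures per individual, restricted by partner rank.

    For focal *i* the bouts considered are those in dyads {i, j} with
    normDS_j < normDS_i (``given``), normDS_j > normDS_i (``received``) or
    any partner (``all``).  All bouts in a qualifying dyad count regardless
    of who initiated.  DII is bout-weighted by default (pooled
    least-frequent counts over pooled totals across dyads);
    ``dyad_mean`` averages per-dyad DIIs instead.
    """
    ranked = set(ranks.individuals)
    for b in bouts:
        if b.aggressor_id not in ranked or b.victim_id not in ranked:
            raise ValidationError(
                f"bout {b.bout_id}: participant missing from rank table")

    dyads: dict[tuple[str, str], list[AggressionBout]] = {}
    for b in bouts:
        key = tuple(sorted((b.aggressor_id, b.victim_id)))
        dyads.setdefault(key, []).append(b)

    out: dict[str, ToleranceProfile] = {}
    for focal in ranks.individuals:
        nf = ranks.norm_of(focal)
        restricted: list[list[AggressionBout]] = []
        for (x, y), dyad_bouts in dyads.items():
            if focal not in (x, y):
                continue
            partner = y if focal == x else x
            npart = ranks.norm_of(partner)
            if direction == "given" and not (npart < nf):
                continue
            if direction == "received" and not (npart > nf):
                continue
            restricted.append(dyad_bouts)

        total = sum(len(d) for d in restricted)
        if total < max(min_bouts, 1):
            out[focal] = ToleranceProfile(focal, direction, None, None, None, total)
            continue

        if dii_mode == "pooled":
            least = sum(min(sum(1 for b in d if b.aggressor_id == d[0].aggressor_id),
                            sum(1 for b in d if b.aggressor_id != d[0].aggressor_id))
                        for d in restricted)
            dii = least / total
        else:
            dii = float(np.mean([dyad_dii(d) for d in restricted]))
        counter = 100.0 * sum(1 for d in restricted for b in d if b.counter) / total
        intensity = 100.0 * sum(1 for d in restricted for b in d if b.contact) / total
        out[focal] = ToleranceProfile(focal, direction, dii, counter, intensity, total)
    return out


def feeding_proximity(scans: Sequence[ProximityScan], focal_id: str,
                      min_scans: int = DEFAULT_MIN_BOUTS) -> Optional[float]:
    """Percent of feeding scans with an independent neighbour within 1 m.

    Non-feeding scans never count.  Returns ``None`` when the focal has
    fewer than ``min_scans`` feeding scans.
    """
    feeding = [s for s in scans if s.focal_id == focal_id and s.feeding]
    if len(feeding) < max(min_scans, 1):
        return None
    near = sum(1 for s in feeding if s.neighbor_within_1m)
    return 100.0 * near / len(feeding)


# ---------------------------------------------------------------------------
# Species-level composite dominance-style index
# ---------------------------------------------------------------------------

@dataclass
class SpeciesStyleIndex:
    """Species means, cross-species z-scores and the composite index.

    Aggression intensity is negated before z-scoring so each z-score, and
    hence the composite (their mean), increases with tolerance.
    """

    species_id: str
    mean_dii: float
    mean_counter: float
    mean_intensity: float
    z_dii: float = math.nan
    z_counter: float = math.nan
    z_intensity: float = math.nan
    composite: float = math.nan


def composite_index(
    profiles_by_group: Mapping[str, Iterable[ToleranceProfile]],
    group_meta: Sequence[GroupMeta],
    log: Optional[list[str]] = None,
) -> list[SpeciesStyleIndex]:
    """Species composite dominance-style index.

    Steps: (i) mean of each measure over the individuals of a group,
    (ii) mean over the groups of a species, (iii) z-score of each measure
    across species (sample SD, intensity negated), (iv) composite = mean of
    the three z-scores.  Species missing any measure are excluded and
    logged; fewer than two complete species, or a zero cross-species SD, is
    an error.
    """
    species_of = {g.group_id: g.species_id for g in group_meta}
    group_means: dict[str, dict[str, list[float]]] = {}
    for group_id, profs in profiles_by_group.items():
        if group_id not in species_of:
            raise ValidationError(f"group {group_id} missing from group metadata")
        sp = species_of[group_id]
        means: dict[str, float] = {}
        for name, get in (("dii", lambda p: p.dii),
                          ("counter", lambda p: p.counter_pct),
                          ("intensity", lambda p: p.intensity_pct)):
            vals = [get(p) for p in profs if get(p) is not None]
            if vals:
                means[name] = float(np.mean(vals))
        if means:
            bucket = group_means.setdefault(sp, {"dii": [], "counter": [],
                                                 "intensity": []})
            for name, v in means.items():
                bucket[name].append(v)

    complete: list[SpeciesStyleIndex] = []
    for sp in sorted(group_means):
        bucket = group_means[sp]
        if all(bucket[m] for m in ("dii", "counter", "intensity")):
            complete.append(SpeciesStyleIndex(
                species_id=sp,
                mean_dii=float(np.mean(bucket["dii"])),
                mean_counter=float(np.mean(bucket["counter"])),
                mean_intensity=float(np.mean(bucket["intensity"]))))
        elif log is not None:
            missing = [m for m in ("dii", "counter", "intensity") if not bucket[m]]
            log.append(f"species {sp} excluded from composite index: "
                       f"missing {', '.join(missing)}")

    if len(complete) < 2:
        raise ValidationError(
            f"composite index requires >= 2 complete species, got {len(complete)}")

    for name, attr, sign in (("dii", "mean_dii", 1.0),
                             ("counter", "mean_counter", 1.0),
                             ("intensity", "mean_intensity", -1.0)):
        vals = np.array([sign * getattr(s, attr) for s in complete])
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ValidationError(
                f"composite index: zero cross-species SD for {name}")
        z = (vals - vals.mean()) / sd
        for s, zv in zip(complete, z):
            setattr(s, f"z_{name}", float(zv))
    for s in complete:
        s.composite = (s.z_dii + s.z_counter + s.z_intensity) / 3.0
    return complete
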