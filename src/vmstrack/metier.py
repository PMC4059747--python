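"""Métier discovery and classification from logbook catch profiles.

A métier (DCF level 5–6 fishing-activity category, e.g. bottom otter
trawling for demersal species) shows up in logbooks as a characteristic
catch composition.  Métiers are discovered by k-medoids clustering of
catch profiles — PAM run CLARA-style on random subsamples for large
datasets — under the Bray–Curtis dissimilarity

    BCD(i, j) = 1 - 2 * C_ij / (S_i + S_j)

where C_ij sums, over the species common to both records, the lesser of
the two catches, and S_i, S_j are the records' total catches.  The
number of clusters is chosen by maximising the average silhouette width
(ASW).  New records are classified by fuzzy membership to the medoids,
softening the crisp nearest-medoid rule.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist as _sc_cdist

DISTANCES = ("euclidean", "manhattan", "bray_curtis")


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity between two nonnegative catch profiles.

    0 for equal profiles, 1 for disjoint species supports.  Raises if both
    profiles are all-zero (undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    si = x.sum()
    sj = y.sum()
    if si + sj == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero profiles")
    c = np.minimum(x, y).sum()
    return float(1.0 - 2.0 * c / (si + sj))


def pairwise_distance(X, Y=None, distance: str = "bray_curtis") -> np.ndarray:
    """Distance matrix between rows of X and Y (Y defaults to X)."""
    X = np.asarray(X, dtype=float)
    Y = X if Y is None else np.asarray(Y, dtype=float)
    if distance == "euclidean":
        return _sc_cdist(X, Y, metric="euclidean")
    if distance == "manhattan":
        return _sc_cdist(X, Y, metric="cityblock")
    if distance == "bray_curtis":
        si = X.sum(axis=1)[:, None]
        sj = Y.sum(axis=1)[None, :]
        tot = si + sj
        if np.any(tot == 0):
            raise ValueError("Bray-Curtis undefined for two all-zero profiles")
        c = np.empty((X.shape[0], Y.shape[0]))
        chunk = max(1, int(2**25 / max(Y.shape[0] * X.shape[1], 1)))  # cap temporaries
        for i in range(0, X.shape[0], chunk):
            c[i:i + chunk] = np.minimum(X[i:i + chunk, None, :], Y[None, :, :]).sum(axis=2)
        return 1.0 - 2.0 * c / tot
    raise ValueError(f"unknown distance: {distance}")


def _build(D: np.ndarray, k: int) -> list[int]:
    """PAM BUILD phase: greedy minimum-cost seeding."""
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dnear = D[:, medoids].min(axis=1)
        # gain of adding each candidate: total reduction in nearest-distance
        gains = np.maximum(dnear[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return medoids


#: instance sizes up to which pam solves the medoid problem exactly by
#: enumeration (guarantees the global optimum where BUILD+SWAP could stop
#: in a swap-local optimum; also cheaper there).
EXACT_ENUMERATION_LIMIT = 2000


def _pam_exact(D: np.ndarray, k: int) -> list[int]:
    from itertools import combinations

    best_cost = np.inf
    best: tuple[int, ...] | None = None
    for combo in combinations(range(D.shape[0]), k):
        cost = D[:, combo].min(axis=1).sum()
        if cost < best_cost - 1e-15:
            best_cost = cost
            best = combo
    return list(best)


def pam(data, k: int, distance: str = "bray_curtis", dist_matrix=None):
    """Partitioning Around Medoids.

    Small instances (C(n, k) up to ~2000 candidate medoid sets) are solved
    exactly by enumeration; larger ones by the classic greedy BUILD seeding
    followed by best-improvement SWAP steps to a swap-local optimum.

    Returns (medoid_indices, labels, total_cost) where cost is the sum of
    distances from each point to its nearest medoid.  Deterministic; ties
    resolved by lowest index.
    """
    from math import comb

    if dist_matrix is not None:
        D = np.asarray(dist_matrix, dtype=float)
        n = D.shape[0]
    else:
        X = np.asarray(data, dtype=float)
        n = X.shape[0]
        D = pairwise_distance(X, distance=distance)
    if not (1 <= k < n):
        raise ValueError(f"k must satisfy 1 <= k < n (got k={k}, n={n})")

    if comb(n, k) <= EXACT_ENUMERATION_LIMIT:
        medoids = sorted(_pam_exact(D, k))
        Dm = D[:, medoids]
        labels = np.argmin(Dm, axis=1)
        return medoids, labels, float(Dm[np.arange(n), labels].sum())

    medoids = _build(D, k)
    while True:
        Dm = D[:, medoids]  # (n, k)
        order = np.argsort(Dm, axis=1, kind="stable")
        d1 = Dm[np.arange(n), order[:, 0]]
        a1 = order[:, 0]
        d2 = Dm[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        best_delta = -1e-12
        best_swap = None
        in_medoids = np.zeros(n, dtype=bool)
        in_medoids[medoids] = True
        candidates = np.where(~in_medoids)[0]
        Dh = D[:, candidates]  # (n, m)
        for i in range(k):
            served = (a1 == i)[:, None]
            # served points fall back to min(second choice, new medoid);
            # others can only gain from the new medoid
            delta = np.where(served,
                             np.minimum(Dh, d2[:, None]) - d1[:, None],
                             np.minimum(Dh - d1[:, None], 0.0))
            totals = delta.sum(axis=0)
            j = int(np.argmin(totals))
            if totals[j] < best_delta:
                best_delta = float(totals[j])
                best_swap = (i, int(candidates[j]))
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]

    medoids = sorted(medoids)
    Dm = D[:, medoids]
    labels = np.argmin(Dm, axis=1)
    cost = float(Dm[np.arange(n), labels].sum())
    return medoids, labels, cost


def clara(data, k: int, n_samples: int = 100, sample_size: int = 1000,
          distance: str = "bray_curtis", seed: int | None = None):
    """CLARA: PAM on random subsamples, scored on the full dataset.

    Each subsample (after the first, augmented with the best medoids so
    far) is clustered with PAM; all data are assigned to the sample's
    medoids and the medoid set with the lowest full-data average
    dissimilarity is kept.  Deterministic for a fixed seed.  If
    ``sample_size >= n`` a single full-data PAM is run.

    Returns (medoid_indices, labels, avg_dissimilarity).
    """
    X = np.asarray(data, dtype=float)
    n = X.shape[0]
    if sample_size < k:
        raise ValueError("sample_size must be >= k")
    if sample_size >= n:
        medoids, labels, cost = pam(X, k, distance)
        return medoids, labels, cost / n

    rng = np.random.default_rng(seed)
    best: tuple[float, list[int], np.ndarray] | None = None
    for _ in range(n_samples):
        idx = rng.choice(n, size=sample_size, replace=False)
        if best is not None:
            # classic CLARA refinement: keep the current best medoids in play
            idx = np.unique(np.concatenate([idx, np.asarray(best[1])]))
        sub_medoids, _, _ = pam(X[idx], k, distance)
        medoids = [int(idx[m]) for m in sub_medoids]
        Dm = pairwise_distance(X, X[medoids], distance)
        labels = np.argmin(Dm, axis=1)
        avg = float(Dm[np.arange(n), labels].mean())
        if best is None or avg < best[0]:
            best = (avg, medoids, labels)
    avg, medoids, labels = best
    return medoids, labels, avg


def asw(data, assignment, distance: str = "bray_curtis", dist_matrix=None) -> float:
    """Average silhouette width in [-1, 1].

    s(i) = (b_i - a_i) / max(a_i, b_i) with a_i the mean dissimilarity to
    the own cluster (excluding self) and b_i the smallest mean
    dissimilarity to another cluster.  Singletons score 0, as does the
    degenerate a = b = 0 case.  Requires >= 2 nonempty clusters.
    """
    labels = np.asarray(assignment)
    if dist_matrix is not None:
        D = np.asarray(dist_matrix, dtype=float)
    else:
        D = pairwise_distance(np.asarray(data, dtype=float), distance=distance)
    return _asw_from_matrix(D, labels)


def _asw_from_matrix(D: np.ndarray, labels: np.ndarray) -> float:
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n = len(labels)
    onehot = (labels[:, None] == uniq[None, :]).astype(float)
    counts = onehot.sum(axis=0)
    sums = D @ onehot  # (n, k): total dissimilarity to each cluster
    own = (labels[:, None] == uniq[None, :])
    own_count = counts[np.searchsorted(uniq, labels)]
    a = np.where(own_count > 1,
                 sums[own] / np.maximum(own_count - 1, 1), 0.0)
    other = np.where(own, np.inf, sums / counts[None, :])
    b = other.min(axis=1)
    denom = np.maximum(a, b)
    s = np.zeros(n)
    np.divide(b - a, denom, out=s, where=denom > 0)
    s[own_count == 1] = 0.0
    return float(s.mean())


@dataclass
class MetierModel:
    """Medoid catch profiles + distance + fuzziness defining a métier classifier."""

    species: list[str]
    medoids: np.ndarray  # (k, n_species), actual training records
    labels: list[str]  # DCF strings, unique
    distance: str = "bray_curtis"
    fuzziness: float = 2.0

    def __post_init__(self):
        self.medoids = np.asarray(self.medoids, dtype=float)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("métier labels must be unique")
        if self.fuzziness <= 1.0:
            raise ValueError("fuzziness m must be > 1")

    @property
    def k(self) -> int:
        return self.medoids.shape[0]

    def save(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["label"] + list(self.species))
            for lab, row in zip(self.labels, self.medoids):
                w.writerow([lab] + [f"{v:.10g}" for v in row])

    @classmethod
    def load(cls, path, distance: str = "bray_curtis", fuzziness: float = 2.0) -> "MetierModel":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        species = rows[0][1:]
        labels = [r[0] for r in rows[1:]]
        medoids = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
        return cls(species=species, medoids=medoids, labels=labels,
                   distance=distance, fuzziness=fuzziness)


def profiles_matrix(records, species: list[str] | None = None,
                    per_day: bool = False) -> tuple[np.ndarray, list[str]]:
    """Stack logbook records into a (n, n_species) catch matrix.

    ``species=None`` uses the sorted union of species seen.  With
    ``per_day`` each profile is divided by its trip length in days
    (standardisation per trip temporal length)."""
    if species is None:
        universe: set[str] = set()
        for r in records:
            universe.update(r.catches)
        species = sorted(universe)
    idx = {s: j for j, s in enumerate(species)}
    X = np.zeros((len(records), len(species)))
    for i, r in enumerate(records):
        for s, q in r.catches.items():
            if s in idx:
                X[i, idx[s]] = q
        if per_day:
            days = max(r.duration_days, 1e-9)
            X[i] /= days
    return X, species


def remove_outliers(X: np.ndarray, distance: str = "bray_curtis",
                    quantile: float = 0.99) -> np.ndarray:
    """Indices of records kept after outlier removal.

    A record is an outlier when its nearest-neighbour dissimilarity exceeds
    the ``quantile`` of all nearest-neighbour dissimilarities.
    """
    D = pairwise_distance(X, distance=distance)
    np.fill_diagonal(D, np.inf)
    nn = D.min(axis=1)
    return np.where(nn <= np.quantile(nn, quantile))[0]


def discover_metiers(records, k_range, distance: str = "bray_curtis",
                     n_samples: int = 100, sample_size: int = 1000,
                     seed: int | None = None, outlier_removal: bool = False,
                     per_day: bool = False):
    """Search k over ``k_range``, keeping the clustering with maximal ASW.

    Returns (MetierModel, silhouette_profile) where the profile is the list
    of (k, ASW) pairs over the searched range.  Medoids are actual records;
    provisional labels are "M1".."Mk" pending DCF identification.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k_range")
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    X, species = profiles_matrix(records, per_day=per_day)
    keep = np.arange(len(X))
    if outlier_removal:
        keep = remove_outliers(X, distance)
        X = X[keep]

    D_full = pairwise_distance(X, distance=distance)
    profile: list[tuple[int, float]] = []
    best: tuple[float, int, list[int]] | None = None
    for k in k_range:
        medoids, labels, _ = clara(X, k, n_samples=n_samples,
                                   sample_size=sample_size,
                                   distance=distance, seed=seed)
        try:
            score = _asw_from_matrix(D_full, labels)
        except ValueError:
            score = float("-inf")  # degenerate single-cluster assignment
        profile.append((k, score))
        if best is None or score > best[0]:
            best = (score, k, medoids)

    _, k_best, medoids = best
    model = MetierModel(species=species, medoids=X[medoids],
                        labels=[f"M{i + 1}" for i in range(k_best)],
                        distance=distance)
    return model, profile


def load_reference_profiles(path) -> dict[str, dict[str, float]]:
    """Read reference métier catch profiles (CSV: label + species columns)."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    species = rows[0][1:]
    return {r[0]: {s: float(v) for s, v in zip(species, r[1:])} for r in rows[1:]}


def save_reference_profiles(references: dict[str, dict[str, float]], path) -> None:
    species = sorted({s for p in references.values() for s in p})
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label"] + species)
        for lab, prof in references.items():
            w.writerow([lab] + [f"{prof.get(s, 0.0):.10g}" for s in species])


def label_medoids(model: MetierModel, references: dict[str, dict[str, float]]) -> MetierModel:
    """Replace provisional medoid labels with DCF codes from reference profiles.

    Mirrors the manual métier-editing step: each medoid is greedily matched
    (smallest Bray-Curtis on composition-normalised profiles first) to an
    unused reference métier; leftover medoids keep their provisional label.
    """
    species = sorted(set(model.species) | {s for p in references.values() for s in p})
    idx = {s: j for j, s in enumerate(species)}

    def vec(profile: dict[str, float]) -> np.ndarray:
        v = np.zeros(len(species))
        for s, q in profile.items():
            v[idx[s]] = q
        tot = v.sum()
        return v / tot if tot > 0 else v

    med = np.zeros((model.k, len(species)))
    for i, row in enumerate(model.medoids):
        for s, q in zip(model.species, row):
            med[i, idx[s]] = q
        med[i] /= max(med[i].sum(), 1e-300)
    refs = {name: vec(p) for name, p in references.items()}

    cand = sorted((bray_curtis(med[i], rv), i, name)
                  for i in range(model.k) for name, rv in refs.items())
    labels = list(model.labels)
    used_i: set[int] = set()
    used_n: set[str] = set()
    for d, i, name in cand:
        if i in used_i or name in used_n:
            continue
        labels[i] = name
        used_i.add(i)
        used_n.add(name)
    return MetierModel(species=list(model.species), medoids=model.medoids.copy(),
                       labels=labels, distance=model.distance,
                       fuzziness=model.fuzziness)


def classify(records, model: MetierModel):
    """Fuzzy classification of catch records against a fitted model.

    Membership to medoid c is  u_c = d_c^(-2/(m-1)) / sum_c' d_c'^(-2/(m-1));
    a zero distance gives full membership to that medoid (ties split
    equally), and the hard label is the argmax (lowest index on ties).
    All-zero records are unclassifiable (NaN memberships, None label).

    Returns (memberships (n, k), hard_labels list, n_unclassifiable).
    """
    X, _ = profiles_matrix(records, species=list(model.species))
    # new species in the records are absent from the model's universe and,
    # equivalently, zero in every medoid: they contribute only to S_i
    universe: set[str] = set(model.species)
    extra: set[str] = set()
    for r in records:
        extra.update(set(r.catches) - universe)
    if extra:
        Xe, _ = profiles_matrix(records, species=sorted(extra))
        X = np.hstack([X, Xe])
        M = np.hstack([model.medoids, np.zeros((model.k, len(extra)))])
    else:
        M = model.medoids

    n = X.shape[0]
    U = np.full((n, model.k), np.nan)
    hard: list[str | None] = [None] * n
    bad = 0
    nonzero = X.sum(axis=1) > 0
    if np.any(nonzero):
        Dm = pairwise_distance(X[nonzero], M, model.distance)
        expo = -2.0 / (model.fuzziness - 1.0)
        u = np.zeros_like(Dm)
        for r, drow in enumerate(Dm):
            zero = drow == 0
            if zero.any():
                u[r, zero] = 1.0 / zero.sum()
            else:
                # log-space for numerical stability as m -> 1+ (expo -> -inf)
                logw = expo * np.log(drow)
                logw -= logw.max()
                w = np.exp(logw)
                u[r] = w / w.sum()
        U[nonzero] = u
        for i, r in zip(np.where(nonzero)[0], range(u.shape[0])):
            hard[i] = model.labels[int(np.argmax(u[r]))]
    bad = int((~nonzero).sum())
    return U, hard, bad
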