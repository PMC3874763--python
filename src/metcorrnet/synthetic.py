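"""Synthetic metabolite profiles and toy reconstructions with known truth.

The profile generator emulates the study design the analysis targets:
two experimental conditions with ~30 biological replicates each, ~52
metabolite peaks, positive (log-normal) peak areas, a per-group
correlation structure with planted differentially correlated pairs,
pooled-QC injections, sporadic missing values and occasional gross
outliers several standard deviations from the group mean. The network
generator emits small random—but connected—reaction sets as SBML,
together with independently computed all-pairs shortest path lengths,
so the full pipeline is testable without any external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metnet
from .metnet import MetabolicNetwork, Reaction, Species
from .profiles import ProfileMatrix

__all__ = [
    "SimulationSpec",
    "GoldStandard",
    "simulate_profiles",
    "simulate_network",
]


@dataclass
class SimulationSpec:
    """Study conditions for one simulated profiling experiment.

    Defaults mirror the design the method was developed for: two oxygen
    conditions x 30 replicates for one cohort, 52 metabolite peaks,
    log-normal positive peak areas (correlation structure imposed on the
    log scale), 5 pooled-QC injections, 2% sporadic missing values and
    1% gross outliers at 5 SD. ``planted_pairs`` holds
    ``(i, j, {group: r})`` triples spliced into the per-group target
    correlation matrices (identity elsewhere unless ``correlation``
    supplies full matrices).
    """

    groups: tuple[str, ...] = ("normoxia", "hypoxia")
    cohort: str = "cells"
    n_samples: int = 30
    n_metabolites: int = 52
    planted_pairs: tuple[tuple[int, int, dict[str, float]], ...] = ()
    correlation: dict[str, np.ndarray] | None = None
    lognormal: bool = True
    log_mean: float = 10.0  # log peak area location (exp -> ~2e4 counts)
    log_sd: float = 0.4  # biological CV ~40% on the natural scale
    n_qc: int = 5
    qc_cv: float = 0.05
    missing_rate: float = 0.02
    outlier_rate: float = 0.01
    outlier_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_metabolites < 2:
            raise ValueError("need at least 2 samples and 2 metabolites")
        for rate in (self.missing_rate, self.outlier_rate):
            if not 0 <= rate < 1:
                raise ValueError("rates must lie in [0, 1)")
        for i, j, targets in self.planted_pairs:
            if not 0 <= i < self.n_metabolites or not 0 <= j < self.n_metabolites:
                raise ValueError("planted pair index out of range")
            if i == j:
                raise ValueError("planted pair must involve two metabolites")
            for r in targets.values():
                if not -1 < r < 1:
                    raise ValueError(f"planted correlation {r} outside (-1, 1)")


@dataclass
class GoldStandard:
    """Ground truth accompanying a simulation.

    ``planted`` maps metabolite-id pairs to their true per-group
    correlations; ``path_lengths`` (network simulations) holds all-pairs
    shortest path lengths computed by an exhaustive search independent
    of the package's BFS.
    """

    planted: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    target_correlation: dict[str, np.ndarray] = field(default_factory=dict)
    psd_adjusted: bool = False
    path_lengths: dict[tuple[str, str], int | None] = field(default_factory=dict)


def _nearest_psd(c: np.ndarray, tol: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Eigenvalue-clipped PSD repair preserving the unit diagonal."""
    vals, vecs = np.linalg.eigh(c)
    if vals.min() >= -tol:
        return c, False
    vals = np.clip(vals, tol, None)
    repaired = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired, True


def _metabolite_ids(n: int) -> list[str]:
    return [f"met{str(i + 1).zfill(2)}" for i in range(n)]


def simulate_profiles(spec: SimulationSpec) -> tuple[ProfileMatrix, GoldStandard]:
    """Draw a profile matrix realising the spec's correlation structure.

    Per group, samples come from a multivariate normal with the target
    correlation matrix (identity plus planted pairs, or explicit
    matrices; a nearest-PSD repair is applied and reported when the
    target is indefinite). With ``lognormal`` the draws are exponentiated
    so peak areas are positive and correlations hold on the log scale.
    Missing values (completely at random) and ``outlier_sd``-SD outliers
    are injected afterwards. Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    mids = _metabolite_ids(spec.n_metabolites)
    gold = GoldStandard()

    frames = []
    meta_rows = []
    for group in spec.groups:
        if spec.correlation is not None:
            corr = np.array(spec.correlation[group], dtype=float)
        else:
            corr = np.eye(spec.n_metabolites)
        for i, j, targets in spec.planted_pairs:
            if group in targets:
                corr[i, j] = corr[j, i] = targets[group]
                gold.planted.setdefault((mids[i], mids[j]), {})[group] = targets[group]
        corr, adjusted = _nearest_psd(corr)
        gold.psd_adjusted = gold.psd_adjusted or adjusted
        gold.target_correlation[group] = corr

        z = rng.multivariate_normal(
            mean=np.zeros(spec.n_metabolites), cov=corr, size=spec.n_samples,
            method="cholesky",
        )
        x = spec.log_mean + spec.log_sd * z
        if spec.lognormal:
            x = np.exp(x)
        df = pd.DataFrame(
            x,
            columns=mids,
            index=[f"{group[:1].upper()}{k + 1:02d}" for k in range(spec.n_samples)],
        )

        # gross outliers first (on observed group statistics), then missingness
        if spec.outlier_rate > 0:
            mask = rng.random(df.shape) < spec.outlier_rate
            mean = df.mean(axis=0).to_numpy()
            sd = df.std(axis=0, ddof=1).to_numpy()
            sign = rng.choice([-1.0, 1.0], size=df.shape)
            bumped = mean + sign * spec.outlier_sd * sd
            values = df.to_numpy()
            values[mask] = np.maximum(bumped, 0.0)[mask]
            df = pd.DataFrame(values, columns=df.columns, index=df.index)
        if spec.missing_rate > 0:
            mask = rng.random(df.shape) < spec.missing_rate
            df = df.mask(pd.DataFrame(mask, columns=df.columns, index=df.index))

        frames.append(df)
        meta_rows += [(s, group, spec.cohort, False) for s in df.index]

    if spec.n_qc > 0:
        pooled = pd.concat(frames).mean(axis=0)
        noise = rng.normal(1.0, spec.qc_cv, size=(spec.n_qc, spec.n_metabolites))
        qc = pd.DataFrame(
            pooled.to_numpy() * np.abs(noise),
            columns=mids,
            index=[f"QC{k + 1:02d}" for k in range(spec.n_qc)],
        )
        frames.append(qc)
        meta_rows += [(s, "", "", True) for s in qc.index]

    values = pd.concat(frames)
    idx = values.index
    profile = ProfileMatrix(
        values=values,
        condition=pd.Series([m[1] for m in meta_rows], index=idx),
        cohort=pd.Series([m[2] for m in meta_rows], index=idx),
        is_qc=pd.Series([m[3] for m in meta_rows], index=idx),
    )
    return profile, gold


# -- toy reconstructions -------------------------------------------------


def _floyd_warshall(species: list[str], reactions: list[Reaction]) -> dict:
    """All-pairs shortest path lengths by plain dynamic programming.

    Deliberately independent of the connectivity-graph / BFS code path:
    adjacency is read straight off the reaction participant lists and
    relaxed with triple loops.
    """
    n = len(species)
    pos = {s: i for i, s in enumerate(species)}
    inf = float("inf")
    dist = [[0 if i == j else inf for j in range(n)] for i in range(n)]
    for rxn in reactions:
        for sa, _ in rxn.consumed:
            for sb, _ in rxn.produced:
                if sa != sb:
                    i, j = pos[sa], pos[sb]
                    dist[i][j] = dist[j][i] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    out = {}
    for i, a in enumerate(species):
        for j, b in enumerate(species):
            if i < j:
                out[(a, b)] = None if dist[i][j] == inf else int(dist[i][j])
    return out


def simulate_network(
    n_species: int,
    n_reactions: int,
    max_participants: int = 2,
    seed: int = 0,
    path=None,
) -> tuple[MetabolicNetwork, GoldStandard]:
    """Random connected reaction network with known shortest paths.

    A spanning chain of conversions guarantees connectivity; additional
    random reactions (up to ``max_participants`` species per side) add
    shortcuts. Species carry synthetic KEGG-style ids (``C90001`` ...) as
    annotations so annotation-based mapping is exercised end to end.
    When ``path`` is given the model is also written there as SBML.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if n_reactions < n_species - 1:
        raise ValueError(
            f"need >= {n_species - 1} reactions to connect {n_species} species"
        )
    rng = np.random.default_rng(seed)
    species = [
        Species(id=f"S{i + 1:02d}", name=f"species {i + 1}", kegg=f"C9{i + 1:04d}")
        for i in range(n_species)
    ]
    sids = [s.id for s in species]
    reactions: list[Reaction] = []
    order = list(rng.permutation(n_species))
    for k in range(1, n_species):  # spanning chain over a random order
        a, b = sids[order[k - 1]], sids[order[k]]
        reactions.append(
            Reaction(id=f"R{k:03d}", consumed=((a, 1.0),), produced=((b, 1.0),))
        )
    for k in range(n_species - 1, n_reactions):
        n_in = int(rng.integers(1, max_participants + 1))
        n_out = int(rng.integers(1, max_participants + 1))
        chosen = rng.choice(n_species, size=min(n_in + n_out, n_species), replace=False)
        ins, outs = chosen[:n_in], chosen[n_in:]
        if len(outs) == 0:
            continue
        reactions.append(
            Reaction(
                id=f"R{k + 1:03d}",
                consumed=tuple((sids[i], 1.0) for i in ins),
                produced=tuple((sids[i], 1.0) for i in outs),
            )
        )
    net = MetabolicNetwork(species=species, reactions=reactions)
    gold = GoldStandard(path_lengths=_floyd_warshall(sids, reactions))
    if path is not None:
        metnet.write_sbml(net, path)
    return net, gold
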