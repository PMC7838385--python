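"""Node roles (Zi/Pi), top-connectivity genes, module eigengenes, and
their environmental correlations.

Zi is the within-module degree z-score and Pi the among-module
participation coefficient (Guimera-Amaral).  Thresholds Zi > 2.5 and
Pi > 0.62 classify nodes as network hubs (both), module hubs (Zi only),
connectors (Pi only), and peripherals (neither); boundary values fall to
the peripheral side.  A module eigengene is the first principal
component of the module members' standardized abundance profiles across
samples, oriented so that it correlates positively with its members on
average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PipelineError, SignalMatrix
from .rmt import GeneNetwork
from .topology import ModulePartition

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62

NETWORK_HUB = "network_hub"
MODULE_HUB = "module_hub"
CONNECTOR = "connector"
PERIPHERAL = "peripheral"


@dataclass
class NodeRole:
    node: str
    module: int
    k: int  # total degree
    k_within: int  # links into the node's own module
    zi: float
    pi: float
    role: str
    zi_degenerate: bool = False  # module of size 1 or zero spread


def classify(zi: float, pi: float) -> str:
    if zi > ZI_THRESHOLD and pi > PI_THRESHOLD:
        return NETWORK_HUB
    if zi > ZI_THRESHOLD:
        return MODULE_HUB
    if pi > PI_THRESHOLD:
        return CONNECTOR
    return PERIPHERAL


def node_roles(network: GeneNetwork, partition: ModulePartition) -> list[NodeRole]:
    """Zi/Pi role classification for every network node."""
    g = network.graph
    missing = [n for n in g.nodes if n not in partition.node_to_module]
    if missing:
        raise PipelineError(f"partition does not cover nodes: {missing[:5]}")
    mod = partition.node_to_module
    # per-node links into each module
    k_is: dict[str, dict[int, int]] = {n: {} for n in g.nodes}
    for u, v in g.edges:
        k_is[u][mod[v]] = k_is[u].get(mod[v], 0) + 1
        k_is[v][mod[u]] = k_is[v].get(mod[u], 0) + 1
    k_within = {n: k_is[n].get(mod[n], 0) for n in g.nodes}
    # within-module degree statistics per module
    stats_by_module = {}
    for m in set(mod.values()):
        members = [n for n in g.nodes if mod[n] == m]
        vals = np.array([k_within[n] for n in members], dtype=float)
        stats_by_module[m] = (vals.mean(), vals.std(ddof=0), len(members))
    roles = []
    for n in g.nodes:
        k = g.degree(n)
        mean_w, sd_w, size = stats_by_module[mod[n]]
        degenerate = size == 1 or sd_w == 0
        zi = 0.0 if degenerate else (k_within[n] - mean_w) / sd_w
        pi = 1.0 - sum((c / k) ** 2 for c in k_is[n].values()) if k > 0 else 0.0
        roles.append(
            NodeRole(
                node=n,
                module=mod[n],
                k=k,
                k_within=k_within[n],
                zi=float(zi),
                pi=float(pi),
                role=classify(zi, pi),
                zi_degenerate=degenerate,
            )
        )
    return roles


def roles_table(roles: list[NodeRole], annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "node": [r.node for r in roles],
            "module": [r.module for r in roles],
            "k": [r.k for r in roles],
            "k_within": [r.k_within for r in roles],
            "Zi": [r.zi for r in roles],
            "Pi": [r.pi for r in roles],
            "role": [r.role for r in roles],
        }
    ).set_index("node")
    if annotation is not None:
        cols = [c for c in ("gene_family", "category", "lineage") if c in annotation.columns]
        df = df.join(annotation[cols], how="left")
    return df


def top_connectivity_genes(network: GeneNetwork, k: int = 5) -> list[tuple[str, int]]:
    """Top-k nodes by degree; ties broken lexicographically by gene id."""
    if network.n == 0:
        raise PipelineError("empty network")
    ranked = sorted(network.graph.degree(), key=lambda nd: (-nd[1], nd[0]))
    return ranked[:k]


@dataclass
class ModuleEigengene:
    module: int
    scores: pd.Series  # sample-length eigengene E
    variance_explained: float
    flipped: bool  # orientation flag
    n_genes: int


def module_eigengene(
    matrix: SignalMatrix,
    partition: ModulePartition,
    top_k_modules: int = 5,
) -> list[ModuleEigengene]:
    """First-principal-component eigengene of each of the largest modules.

    Member gene profiles are z-scored across samples; E is the first
    right-singular vector of the standardized module matrix (unit-norm
    gene loadings), sign-oriented so the mean correlation between E and
    the member profiles is positive.  A single-gene module's eigengene
    is that gene's standardized profile.
    """
    values = matrix.values
    out = []
    for m in partition.modules_by_size()[:top_k_modules]:
        members = [g for g in partition.members(m) if g in values.index]
        if not members:
            continue
        x = values.loc[members].to_numpy(dtype=float)
        sd = x.std(axis=1, ddof=0)
        keep = sd > 0
        x = x[keep]
        if x.shape[0] == 0:
            continue
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=0, keepdims=True)
        if z.shape[0] == 1:
            scores = z[0]
            var_explained = 1.0
        else:
            u, s, vt = np.linalg.svd(z, full_matrices=False)
            scores = vt[0] * s[0]
            var_explained = float(s[0] ** 2 / (s**2).sum())
        mean_corr = np.mean([np.corrcoef(scores, row)[0, 1] for row in z])
        flipped = mean_corr < 0
        if flipped:
            scores = -scores
        out.append(
            ModuleEigengene(
                module=int(m),
                scores=pd.Series(scores, index=values.columns, name=f"module{m}"),
                variance_explained=var_explained,
                flipped=bool(flipped),
                n_genes=int(z.shape[0]),
            )
        )
    return out


@dataclass
class EnvCorrelation:
    module: int
    variable: str
    rho: float | None
    p: float | None
    flagged: bool = False  # constant variable: rho undefined


def env_correlation(
    eigengenes: list[ModuleEigengene], env: pd.DataFrame
) -> list[EnvCorrelation]:
    """Spearman rank correlation of each eigengene with each variable.

    Mid-ranks for ties, two-sided p.  Environment rows must cover the
    eigengene samples; constant variables are flagged.
    """
    out = []
    for eg in eigengenes:
        missing = [s for s in eg.scores.index if s not in env.index]
        if missing:
            raise PipelineError(f"env table missing samples: {missing[:5]}")
        sub = env.loc[eg.scores.index]
        for var in env.columns:
            v = sub[var].to_numpy(dtype=float)
            if np.all(v == v[0]):
                out.append(EnvCorrelation(eg.module, var, None, None, flagged=True))
                continue
            rho, p = stats.spearmanr(eg.scores.to_numpy(), v)
            out.append(EnvCorrelation(eg.module, var, float(rho), float(p)))
    return out


def env_correlation_table(correlations: list[EnvCorrelation]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "module": [c.module for c in correlations],
            "variable": [c.variable for c in correlations],
            "rho": [c.rho for c in correlations],
            "p": [c.p for c in correlations],
            "flagged": [c.flagged for c in correlations],
        }
    )
    return df
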