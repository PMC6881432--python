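"""Enrichment statistics: hypergeometric TF-target tests, GOstat-style
functional-class enrichment, Benjamini-Hochberg adjustment, and multi-set
intersection tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p = P(X >= k) of drawing ``k`` successes in
    ``n`` draws from a universe of ``N`` with ``K`` successes."""
    if not (0 <= k <= n <= N) or not 0 <= K <= N or k > K:
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def phasecore_tf(network, core_genes, min_enriched: int = 3,
                 alpha: float = 0.05, universe=None) -> pd.DataFrame:
    """TFs whose target sets are over-represented among the core genes.

    Per TF: ``k`` = targets that are core genes, ``n`` = target count,
    ``K`` = core genes in the universe, ``N`` = universe size (the network's
    gene universe by default).  TFs with fewer than ``min_enriched``
    overlapping targets are dropped before BH adjustment across the
    remaining TFs; a TF is a hit ("PhaseCoreTF") when q < ``alpha``.
    """
    core = pd.Index(core_genes)
    if len(core) == 0:
        raise ValueError("empty core gene set")
    edges = network.edges if hasattr(network, "edges") else network
    if universe is None:
        universe = pd.Index(edges["tf"]).union(pd.Index(edges["target"]))
    universe = pd.Index(universe)
    core = core.intersection(universe)
    N, K = len(universe), len(core)
    rows = []
    for tf, sub in edges.groupby("tf", sort=False):
        targets = pd.Index(sub["target"]).intersection(universe)
        n = len(targets)
        k = len(targets.intersection(core))
        p = hypergeom_p(k, n, K, N) if n else 1.0
        rows.append((tf, k, n, K, N, p))
    out = pd.DataFrame(rows, columns=["tf", "k", "n", "K", "N", "p"])
    out["kept"] = out["k"] >= min_enriched
    out["drop_reason"] = np.where(out["kept"], "",
                                  f"fewer than {min_enriched} core targets")
    out["q"] = np.nan
    if out["kept"].any():
        out.loc[out["kept"], "q"] = bh_adjust(out.loc[out["kept"], "p"])
    out["is_phasecore_tf"] = out["kept"] & (out["q"] < alpha)
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def functional_enrichment(gene_list, collection: dict[str, set],
                          universe, min_overlap: int = 3) -> pd.DataFrame:
    """GOstat-style functional-class enrichment of a gene list.

    Per set, the 2x2 table (in-list x in-set) is tested by chi-squared
    without continuity correction, switching to the two-sided Fisher exact
    test when any expected cell is below 5.  Sets overlapping the list by
    fewer than ``min_overlap`` genes are dropped (with reason); BH is
    applied across the kept sets.
    """
    genes = pd.Index(gene_list)
    universe = pd.Index(universe)
    if len(genes) == 0:
        raise ValueError("empty gene list")
    genes = genes.intersection(universe)
    rows = []
    for name, members in collection.items():
        members = pd.Index(members).intersection(universe)
        a = len(genes.intersection(members))
        b = len(genes) - a
        c = len(members) - a
        d = len(universe) - a - b - c
        table = np.array([[a, b], [c, d]], float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        if (expected < 5).any():
            p = stats.fisher_exact(table, alternative="two-sided")[1]
            method = "fisher"
        else:
            p = stats.chi2_contingency(table, correction=False)[1]
            method = "chi2"
        rows.append((name, a, len(genes), len(members), len(universe),
                     method, p))
    out = pd.DataFrame(rows, columns=["set", "k", "n", "K", "N", "method", "p"])
    out["kept"] = out["k"] >= min_overlap
    out["drop_reason"] = np.where(out["kept"], "",
                                  f"overlap below {min_overlap}")
    out["q"] = np.nan
    if out["kept"].any():
        out.loc[out["kept"], "q"] = bh_adjust(out.loc[out["kept"], "p"])
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def multiset_intersection_p(sets: dict[str, set], universe_size: int,
                            n_perm: int = 10000, seed: int = 0) -> pd.DataFrame:
    """Permutation test for the intersection of every combination of >= 2
    sets drawn from a common universe.

    For each combination, p is the add-one-smoothed fraction of draws of
    uniform random same-size sets whose intersection is at least the
    observed one.  For pairs the exact hypergeometric upper-tail p is also
    reported as a cross-check.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    for name, s in sets.items():
        if len(s) > universe_size:
            raise ValueError(f"set {name!r} larger than the universe")
    rng = np.random.default_rng(seed)
    names = list(sets)
    sizes = {n: len(sets[n]) for n in names}
    # map members to integer codes inside the universe
    all_members = sorted(set().union(*sets.values()))
    code = {m: i for i, m in enumerate(all_members)}
    obs_sets = {n: np.array(sorted(code[m] for m in sets[n])) for n in names}
    rows = []
    for r in range(2, len(names) + 1):
        for combo in combinations(names, r):
            observed = len(set.intersection(*[set(obs_sets[n]) for n in combo]))
            count = 0
            for _ in range(n_perm):
                inter = None
                for n in combo:
                    draw = rng.choice(universe_size, size=sizes[n], replace=False)
                    s = set(draw)
                    inter = s if inter is None else inter & s
                    if not inter:
                        break
                if inter is not None and len(inter) >= observed:
                    count += 1
            p_perm = (count + 1) / (n_perm + 1)
            p_exact = np.nan
            if r == 2:
                a, b = combo
                p_exact = hypergeom_p(observed, sizes[a], sizes[b],
                                      universe_size)
            rows.append(("&".join(combo), observed, p_perm, p_exact))
    return pd.DataFrame(rows, columns=["sets", "observed", "p_perm", "p_exact"])


# ------------------------------------------------------------- GMT I/O ----

def read_gmt(path: str | Path) -> dict[str, set]:
    """Read a GMT gene-set collection (name, description, members...)."""
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        out[fields[0]] = set(fields[2:])
    return out


def write_gmt(collection: dict[str, set], path: str | Path,
              description: str = "na") -> None:
    lines = ["\t".join([name, description, *sorted(members)])
             for name, members in collection.items()]
    Path(path).write_text("\n".join(lines) + "\n")
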