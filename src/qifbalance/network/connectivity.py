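"""Sparse directed wiring of the two-population QIF network.

Within-population in-degrees are Lorentzian with median K and half-width
``delta0 * sqrt(K)`` (structural heterogeneity); cross-population
in-degrees are fixed at exactly K.  Presynaptic partners are drawn
uniformly without replacement, excluding self-connections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["sample_lorentzian_indegrees", "build_connectivity", "Connectivity"]

_BLOCKS = ("ee", "ei", "ie", "ii")  # post, pre


def sample_lorentzian_indegrees(
    N: int, K: float, delta0: float, rng: np.random.Generator | int, size: int | None = None
) -> np.ndarray:
    """Integer in-degrees from a Lorentzian(K, delta0*sqrt(K)) distribution.

    Inverse-CDF draws rounded to the nearest integer; values outside
    [1, N-1] are resampled (rejection, not clipping, to avoid boundary
    atoms).  With delta0 = 0 every in-degree equals round(K).

    Parameters
    ----------
    N
        Population size (the in-degree can use at most N-1 partners).
    K
        Median in-degree, 1 <= K < N.
    delta0
        Heterogeneity scale; the half-width at half-maximum is
        delta0 * sqrt(K).
    rng
        Seed or numpy Generator.
    size
        Number of draws (default N, one per neuron).
    """
    if not K < N:
        raise ValueError("need K < N")
    if K < 1:
        raise ValueError("need K >= 1")
    if delta0 < 0:
        raise ValueError("delta0 must be >= 0")
    if size is None:
        size = N
    if delta0 == 0:
        return np.full(size, int(round(K)), dtype=np.int64)
    rng = np.random.default_rng(rng)
    hwhm = delta0 * np.sqrt(K)
    out = np.empty(size, dtype=np.int64)
    filled = 0
    attempts = 0
    while filled < size:
        n_draw = max(size - filled, 64)
        u = rng.random(n_draw)
        k = np.round(K + hwhm * np.tan(np.pi * (u - 0.5))).astype(np.int64)
        ok = k[(k >= 1) & (k <= N - 1)]
        attempts += n_draw
        take = min(len(ok), size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
        if attempts > 100 * size and filled < attempts * 0.01:
            raise ValueError("distribution inconsistent with population size")
    return out


@dataclass
class Connectivity:
    """Directed adjacency of the E-I network, stored as per-block edge lists.

    `edges[block]` is a pair (pre, post) of local-index arrays for block in
    {"ee", "ei", "ie", "ii"} (first letter = postsynaptic population).
    `k_ee` and `k_ii` are the sampled within-population in-degrees.
    """

    N_e: int
    N_i: int
    K: int
    delta0_ee: float
    delta0_ii: float
    seed: int
    k_ee: np.ndarray
    k_ii: np.ndarray
    edges: dict = field(repr=False)
    _out_csr: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def N(self) -> int:
        return self.N_e + self.N_i

    def in_degrees(self, block: str) -> np.ndarray:
        """Realized in-degrees of the postsynaptic population of `block`."""
        n = self.N_e if block[0] == "e" else self.N_i
        pre, post = self.edges[block]
        return np.bincount(post, minlength=n)

    def presynaptic(self, block: str, j: int) -> np.ndarray:
        """Presynaptic partners (local indices) of post neuron j in `block`."""
        pre, post = self.edges[block]
        return np.sort(pre[post == j])

    def total_in_degrees(self, which: str) -> np.ndarray:
        """k_tot: within-population plus cross-population in-degrees."""
        if which == "e":
            return self.in_degrees("ee") + self.in_degrees("ei")
        return self.in_degrees("ii") + self.in_degrees("ie")

    # -- simulator view ----------------------------------------------------

    def out_csr(self):
        """Global out-adjacency (indptr, targets) with e = 0..N_e-1, i offset N_e.

        Cached; targets of each presynaptic neuron are all its postsynaptic
        partners in both populations.
        """
        if self._out_csr is None:
            pres, posts = [], []
            off = {"e": 0, "i": self.N_e}
            for block in _BLOCKS:
                pre, post = self.edges[block]
                pres.append(pre + off[block[1]])
                posts.append(post + off[block[0]])
            pre = np.concatenate(pres)
            post = np.concatenate(posts)
            order = np.argsort(pre, kind="stable")
            pre, post = pre[order], post[order]
            indptr = np.zeros(self.N + 1, dtype=np.int64)
            np.add.at(indptr, pre + 1, 1)
            indptr = np.cumsum(indptr)
            self._out_csr = (indptr, post.astype(np.int64))
        return self._out_csr

    # -- IO ----------------------------------------------------------------

    def to_text(self, path) -> None:
        """Edge list `pre_pop pre_id post_pop post_id` with a JSON header line."""
        header = json.dumps(
            {
                "N_e": self.N_e,
                "N_i": self.N_i,
                "K": self.K,
                "delta0_ee": self.delta0_ee,
                "delta0_ii": self.delta0_ii,
                "seed": self.seed,
            }
        )
        with open(path, "w") as fh:
            fh.write("# " + header + "\n")
            for block in _BLOCKS:
                pre, post = self.edges[block]
                pp, qp = block[1], block[0]
                for a, b in zip(pre, post):
                    fh.write(f"{pp} {a} {qp} {b}\n")

    @classmethod
    def from_text(cls, path) -> "Connectivity":
        edges = {b: [[], []] for b in _BLOCKS}
        with open(path) as fh:
            meta = json.loads(fh.readline().lstrip("# "))
            for line in fh:
                pre_pop, pre_id, post_pop, post_id = line.split()
                b = post_pop + pre_pop
                edges[b][0].append(int(pre_id))
                edges[b][1].append(int(post_id))
        edges = {
            b: (np.array(v[0], dtype=np.int64), np.array(v[1], dtype=np.int64))
            for b, v in edges.items()
        }
        conn = cls(
            N_e=meta["N_e"],
            N_i=meta["N_i"],
            K=meta["K"],
            delta0_ee=meta["delta0_ee"],
            delta0_ii=meta["delta0_ii"],
            seed=meta["seed"],
            k_ee=np.bincount(edges["ee"][1], minlength=meta["N_e"]),
            k_ii=np.bincount(edges["ii"][1], minlength=meta["N_i"]),
            edges=edges,
        )
        return conn


def _sample_partners(rng, n_source: int, k: int, exclude: int | None) -> np.ndarray:
    """k distinct presynaptic partners among n_source, excluding `exclude`."""
    if exclude is not None:
        pre = rng.choice(n_source - 1, size=k, replace=False)
        pre[pre >= exclude] += 1
        return pre
    return rng.choice(n_source, size=k, replace=False)


def build_connectivity(
    N_e: int,
    N_i: int,
    K: int,
    delta0_ee: float,
    delta0_ii: float,
    seed: int,
) -> Connectivity:
    """Wire the network: Lorentzian within-population, fixed-K across.

    Every neuron receives exactly K partners from the other population and
    its sampled Lorentzian in-degree from its own population, all drawn
    uniformly without replacement and without self-connections.
    Deterministic in `seed`.
    """
    K = int(K)
    if not (K < N_e and K < N_i):
        raise ValueError("need K < min(N_e, N_i)")
    rng = np.random.default_rng(seed)
    k_ee = sample_lorentzian_indegrees(N_e, K, delta0_ee, rng)
    k_ii = sample_lorentzian_indegrees(N_i, K, delta0_ii, rng)
    edges = {}
    for block, n_post, n_pre, degs in (
        ("ee", N_e, N_e, k_ee),
        ("ei", N_e, N_i, np.full(N_e, K, dtype=np.int64)),
        ("ii", N_i, N_i, k_ii),
        ("ie", N_i, N_e, np.full(N_i, K, dtype=np.int64)),
    ):
        same = block[0] == block[1]
        pres = []
        posts = []
        for j in range(n_post):
            pre = _sample_partners(rng, n_pre, int(degs[j]), j if same else None)
            pres.append(pre)
            posts.append(np.full(len(pre), j, dtype=np.int64))
        edges[block] = (np.concatenate(pres), np.concatenate(posts))
    return Connectivity(
        N_e=N_e,
        N_i=N_i,
        K=K,
        delta0_ee=delta0_ee,
        delta0_ii=delta0_ii,
        seed=seed,
        k_ee=k_ee,
        k_ii=k_ii,
        edges=edges,
    )
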