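"""COI population genetics: haplotypes, networks, TN93, PhiST, Tajima's D.

Haplotype collapsing uses complete deletion (alignment columns containing N
or a gap in any sequence are ignored); the haplotype network is a minimum
spanning network over Hamming distances, a deliberate approximation of TCS
statistical parsimony that preserves the qualitative readout (clade
separation and mutation-step counts) while remaining exactly reproducible.
Pairwise PhiST comes from a two-level AMOVA on pairwise sequence
differences with a permutation test; Tamura-Nei (TN93) distances and
Tajima's D (with the classical beta-distribution p approximation) round out
the toolkit.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

from .chemnet import ChemicalType, ChemotypeNetwork, build_msn
from .compstats import DistanceMatrix

VALID_CHARS = set("ACGTN-")
_PURINES = ("A", "G")
_PYRIMIDINES = ("C", "T")


@dataclass
class Alignment:
    """Equal-length DNA sequences over {A, C, G, T, N, -}."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicated sequence ids")
        if self.seqs:
            L = len(self.seqs[0])
            for sid, s in zip(self.ids, self.seqs):
                if len(s) != L:
                    raise ValueError(f"sequence {sid!r} has length {len(s)} != {L}")
                bad = set(s.upper()) - VALID_CHARS
                if bad:
                    raise ValueError(f"sequence {sid!r} has invalid characters {bad}")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def char_array(self) -> np.ndarray:
        return np.array([list(s) for s in self.seqs])

    def subset(self, ids: Sequence[str]) -> "Alignment":
        pos = {sid: i for i, sid in enumerate(self.ids)}
        return Alignment(list(ids), [self.seqs[pos[i]] for i in ids])

    # ---- I/O ---------------------------------------------------------
    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(s), id=sid, description="")
            for sid, s in zip(self.ids, self.seqs)
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])


def _complete_deletion_sites(aln: Alignment) -> np.ndarray:
    arr = aln.char_array()
    ok = ~np.isin(arr, ["N", "-"]).any(axis=0)
    return np.flatnonzero(ok)


@dataclass
class HaplotypeSet:
    """Unique sequences (over complete-deletion sites) with memberships."""

    labels: list[str]
    sequences: list[str]  # reduced to the compared sites
    members: dict[str, list[str]]
    sites: np.ndarray  # alignment columns used for comparison
    counts_by_population: pd.DataFrame | None = None

    @property
    def n_haplotypes(self) -> int:
        return len(self.labels)

    def counts(self) -> pd.Series:
        return pd.Series({h: len(m) for h, m in self.members.items()}, name="count")

    def table(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "haplotype": self.labels,
                "count": [len(self.members[h]) for h in self.labels],
                "members": [";".join(self.members[h]) for h in self.labels],
            }
        )
        return out


def collapse_haplotypes(
    aln: Alignment, popmap: pd.DataFrame | None = None
) -> HaplotypeSet:
    """Merge identical sequences (complete deletion of N/gap columns).

    Haplotypes are labelled H1, H2, ... by decreasing frequency, ties broken
    by first occurrence in the alignment. ``popmap`` (indexed by sample id,
    with a ``population`` column) adds a population x haplotype count table.
    """
    if aln.n == 0:
        raise ValueError("empty alignment")
    sites = _complete_deletion_sites(aln)
    arr = aln.char_array()[:, sites]
    reduced = ["".join(row) for row in arr]
    first_seen: dict[str, int] = {}
    groups: dict[str, list[str]] = {}
    for i, (sid, seq) in enumerate(zip(aln.ids, reduced)):
        if seq not in groups:
            groups[seq] = []
            first_seen[seq] = i
        groups[seq].append(sid)
    ordered = sorted(groups, key=lambda s: (-len(groups[s]), first_seen[s]))
    labels = [f"H{i + 1}" for i in range(len(ordered))]
    members = {lbl: groups[seq] for lbl, seq in zip(labels, ordered)}
    counts = None
    if popmap is not None:
        rows = []
        for lbl in labels:
            pops = popmap.loc[members[lbl], "population"]
            rows.append(pops.value_counts())
        counts = pd.DataFrame(rows, index=labels).fillna(0).astype(int)
        counts.index.name = "haplotype"
    return HaplotypeSet(
        labels=labels,
        sequences=[s for s in ordered],
        members=members,
        sites=sites,
        counts_by_population=counts,
    )


def hamming_matrix(hs: HaplotypeSet) -> pd.DataFrame:
    arr = np.array([list(s) for s in hs.sequences])
    d = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
    return pd.DataFrame(d, index=hs.labels, columns=hs.labels)


def haplotype_network(
    hs: HaplotypeSet,
    max_link: int | None = None,
    include_alternatives: bool = False,
) -> ChemotypeNetwork:
    """Minimum spanning network over haplotype Hamming distances.

    Edge weights count mutational steps (hatch marks); edges longer than
    ``max_link`` are removed afterwards, which may disconnect clades, echoing
    a parsimony connection limit.
    """
    nodes = [
        ChemicalType(label=lbl, categories=(), members=list(hs.members[lbl]))
        for lbl in hs.labels
    ]
    net = build_msn(nodes, distances=hamming_matrix(hs),
                    include_alternatives=include_alternatives)
    if max_link is not None:
        drop = [
            (u, v)
            for u, v, d in net.graph.edges(data=True)
            if d["weight"] > max_link
        ]
        net.graph.remove_edges_from(drop)
    return net


def tamura_nei_distance(aln: Alignment) -> tuple[DistanceMatrix, list[tuple[str, str]]]:
    """TN93 pairwise distances with pairwise deletion of ambiguous sites.

    Base frequencies are estimated from the two sequences of each pair
    (pooled over the comparable sites). Saturated pairs (a logarithm
    argument <= 0) are returned as NaN and listed in the second element.
    """
    arr = aln.char_array()
    n = aln.n
    d = np.zeros((n, n))
    undefined: list[tuple[str, str]] = []
    valid = np.isin(arr, list("ACGT"))
    for i in range(n):
        for j in range(i + 1, n):
            mask = valid[i] & valid[j]
            m = int(mask.sum())
            if m == 0:
                d[i, j] = d[j, i] = np.nan
                undefined.append((aln.ids[i], aln.ids[j]))
                continue
            a, b = arr[i][mask], arr[j][mask]
            if (a == b).all():
                continue
            pooled = np.concatenate([a, b])
            g = {x: (pooled == x).mean() for x in "ACGT"}
            gR, gY = g["A"] + g["G"], g["C"] + g["T"]
            diff = a != b
            pur = np.isin(a, _PURINES) & np.isin(b, _PURINES)
            pyr = np.isin(a, _PYRIMIDINES) & np.isin(b, _PYRIMIDINES)
            P1 = float((diff & pur).sum()) / m
            P2 = float((diff & pyr).sum()) / m
            Q = float((diff & ~pur & ~pyr).sum()) / m
            k1 = 2.0 * g["A"] * g["G"] / gR if gR > 0 else 0.0
            k2 = 2.0 * g["C"] * g["T"] / gY if gY > 0 else 0.0
            try:
                dist = 0.0
                if k1 > 0:
                    w1 = 1.0 - P1 / k1 - Q / (2.0 * gR)
                    dist += -k1 * np.log(w1) if w1 > 0 else np.nan
                elif P1 > 0:
                    dist = np.nan
                if k2 > 0:
                    w2 = 1.0 - P2 / k2 - Q / (2.0 * gY)
                    dist += -k2 * np.log(w2) if w2 > 0 else np.nan
                elif P2 > 0:
                    dist = np.nan
                if gR > 0 and gY > 0:
                    k3 = 2.0 * (gR * gY - g["A"] * g["G"] * gY / gR
                                - g["C"] * g["T"] * gR / gY)
                    w3 = 1.0 - Q / (2.0 * gR * gY)
                    dist += -k3 * np.log(w3) if w3 > 0 else np.nan
                elif Q > 0:
                    dist = np.nan
            except FloatingPointError:  # pragma: no cover
                dist = np.nan
            if not np.isfinite(dist):
                dist = np.nan
                undefined.append((aln.ids[i], aln.ids[j]))
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(aln.ids), d), undefined


def _pairwise_diff_matrix(aln: Alignment) -> np.ndarray:
    sites = _complete_deletion_sites(aln)
    arr = aln.char_array()[:, sites]
    return (arr[:, None, :] != arr[None, :, :]).sum(axis=2).astype(float)


def _phist(d: np.ndarray, sizes: tuple[int, int]) -> float:
    """Two-level AMOVA PhiST from a squared-distance matrix of two groups."""
    n1, n2 = sizes
    n = n1 + n2
    iu = np.triu_indices(n, 1)
    ss_total = d[iu].sum() / n
    ss_within = 0.0
    for lo, hi in ((0, n1), (n1, n)):
        sub = d[lo:hi, lo:hi]
        k = hi - lo
        if k > 1:
            ss_within += sub[np.triu_indices(k, 1)].sum() / k
    ss_among = ss_total - ss_within
    df_among, df_within = 1, n - 2
    if df_within <= 0:
        return np.nan
    ms_within = ss_within / df_within
    n_c = (n - (n1**2 + n2**2) / n) / df_among
    sigma_a = (ss_among / df_among - ms_within) / n_c
    denom = sigma_a + ms_within
    if denom == 0:
        return np.nan
    return float(sigma_a / denom)


def pairwise_fst(
    aln: Alignment,
    popmap: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    min_pop_size: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PhiST between all population pairs, with permutation p-values.

    PhiST = sigma2_among / (sigma2_among + sigma2_within) from an AMOVA on
    pairwise sequence differences (number of differing sites, complete
    deletion). May be negative. p permutes individuals between the two
    populations with the add-one convention; populations smaller than
    ``min_pop_size`` get PhiST but no p (NaN).
    """
    pops = popmap.loc[aln.ids, "population"]
    names = list(pd.unique(pops))
    if len(names) < 2:
        raise ValueError("need at least 2 populations")
    dmat = _pairwise_diff_matrix(aln)
    fst = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    pval = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    rng = np.random.default_rng(seed)
    idx_by_pop = {p: np.flatnonzero((pops == p).values) for p in names}
    for i, pa in enumerate(names):
        fst.loc[pa, pa] = 0.0
        for pb in names[i + 1:]:
            ia, ib = idx_by_pop[pa], idx_by_pop[pb]
            order = np.concatenate([ia, ib])
            sub = dmat[np.ix_(order, order)]
            obs = _phist(sub, (len(ia), len(ib)))
            fst.loc[pa, pb] = fst.loc[pb, pa] = obs
            if (
                np.isnan(obs)
                or len(ia) < min_pop_size
                or len(ib) < min_pop_size
            ):
                continue
            count = 0
            n_tot = len(order)
            for _ in range(n_perm):
                perm = rng.permutation(n_tot)
                ph = _phist(sub[np.ix_(perm, perm)], (len(ia), len(ib)))
                if not np.isnan(ph) and ph >= obs:
                    count += 1
            p = (1 + count) / (n_perm + 1)
            pval.loc[pa, pb] = pval.loc[pb, pa] = p
    return fst, pval


def tajimas_d(aln: Alignment) -> dict[str, float]:
    """Tajima's D with the beta-distribution p approximation.

    D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)) using the standard constants;
    pi is the mean number of pairwise differences and S the number of
    segregating sites, both over complete-deletion columns. Raises when
    there are no segregating sites.
    """
    n = aln.n
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 sequences")
    sites = _complete_deletion_sites(aln)
    arr = aln.char_array()[:, sites]
    seg = np.array([len(set(col)) > 1 for col in arr.T])
    S = int(seg.sum())
    if S == 0:
        raise ValueError("no segregating sites: Tajima's D undefined")
    diffs = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
    iu = np.triu_indices(n, 1)
    pi = float(diffs[iu].mean())

    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    D = (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))

    # beta approximation over [Dmin, Dmax] with mean 0 and variance 1
    dmin = (2.0 / n - 1.0 / a1) / np.sqrt(e2)
    dmax = (n / (2.0 * (n - 1.0)) - 1.0 / a1) / np.sqrt(e2)
    alpha = -(1.0 + dmin * dmax) * dmax / (dmax - dmin)
    beta = (1.0 + dmin * dmax) * dmin / (dmax - dmin)
    if alpha > 0 and beta > 0:
        x = np.clip((D - dmin) / (dmax - dmin), 0.0, 1.0)
        cdf = stats.beta.cdf(x, beta, alpha)
        p = float(2.0 * min(cdf, 1.0 - cdf))
    else:  # pragma: no cover - degenerate constants at tiny n
        p = np.nan
    return {"D": float(D), "S": float(S), "pi": pi, "p": p}
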