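"""Cuticular-hydrocarbon peak-table handling.

Ingests GC-MS peak tables (colonies x substances), computes linear
(temperature-programmed) retention indices against an n-alkane ladder,
parses shorthand substance names into structural annotations, applies the
abundance/presence filtering rules used for CHC profiles, and produces
closed compositional matrices plus substance-class aggregates.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: canonical CHC substance classes (plus a bucket for co-eluting non-CHCs)
SUBSTANCE_CLASSES = (
    "n-alkane",
    "monomethyl alkane",
    "dimethyl alkane",
    "trimethyl alkane",
    "alkene",
    "alkadiene",
    "alkatriene",
    "methyl-branched alkene",
    "non-hydrocarbon",
)


def infer_class(n_methyl: int, n_double_bonds: int) -> str:
    """Substance class implied by methyl-branch and double-bond counts."""
    if n_methyl < 0 or n_double_bonds < 0:
        raise ValueError("branch/double-bond counts must be non-negative")
    if n_double_bonds == 0:
        if n_methyl == 0:
            return "n-alkane"
        if n_methyl == 1:
            return "monomethyl alkane"
        if n_methyl == 2:
            return "dimethyl alkane"
        return "trimethyl alkane"
    if n_methyl >= 1:
        return "methyl-branched alkene"
    if n_double_bonds == 1:
        return "alkene"
    if n_double_bonds == 2:
        return "alkadiene"
    if n_double_bonds == 3:
        return "alkatriene"
    raise ValueError(f"no class for {n_double_bonds} double bonds")


@dataclass
class Substance:
    """One annotated GC-MS peak.

    ``name`` uses the shorthand grammar parsed by :func:`parse_substance_name`
    (e.g. ``"13-MeC29"``); ``klass`` must be consistent with the branch and
    double-bond counts unless the substance is a non-hydrocarbon.
    """

    id: str
    name: str
    chain_length: int
    n_methyl: int
    n_double_bonds: int
    klass: str
    retention_time: float | None = None
    retention_index: float | None = None

    def __post_init__(self) -> None:
        if self.klass not in SUBSTANCE_CLASSES:
            raise ValueError(f"unknown substance class {self.klass!r}")
        if self.klass != "non-hydrocarbon":
            expected = infer_class(self.n_methyl, self.n_double_bonds)
            if expected != self.klass:
                raise ValueError(
                    f"substance {self.id}: class {self.klass!r} inconsistent with "
                    f"{self.n_methyl} methyl / {self.n_double_bonds} double bonds "
                    f"(expected {expected!r})"
                )


_GREEK = {1: "Me", 2: "DiMe", 3: "TriMe"}
_NAME_RE = re.compile(
    r"^(?:(?P<pos>\d+(?:,\d+)*)-)?(?P<me>Me|DiMe|TriMe)?C(?P<chain>\d+)(?::(?P<db>\d+))?$"
)


def parse_substance_name(name: str) -> Substance:
    """Parse a shorthand CHC name into an annotated :class:`Substance`.

    Grammar (EBNF)::

        name      = [ positions "-" ] [ methyl ] "C" chain [ ":" dbonds ] ;
        positions = integer { "," integer } ;
        methyl    = "Me" | "DiMe" | "TriMe" ;

    ``"C29"`` is nonacosane, ``"13-MeC29"`` 13-methyl nonacosane,
    ``"13,23-DiMeC37"`` 13,23-dimethyl heptatriacontane, ``"C41:2"`` a C41
    alkadiene, ``"13-MeC37:1"`` a methyl-branched heptatriacontene.
    """
    m = _NAME_RE.match(name)
    if m is None:
        # locate the first offending character for the error message
        probe = name
        while probe and _NAME_RE.match(probe) is None:
            probe = probe[:-1]
        raise ValueError(
            f"cannot parse substance name {name!r} (error at position {len(probe)})"
        )
    positions = m.group("pos")
    me = m.group("me")
    n_methyl = {"Me": 1, "DiMe": 2, "TriMe": 3}.get(me, 0)
    if (positions is None) != (me is None):
        raise ValueError(
            f"cannot parse substance name {name!r}: methyl positions and "
            "Me/DiMe/TriMe prefix must appear together"
        )
    if positions is not None and len(positions.split(",")) != n_methyl:
        raise ValueError(
            f"cannot parse substance name {name!r}: {len(positions.split(','))} "
            f"positions given for {_GREEK[n_methyl]}"
        )
    chain = int(m.group("chain"))
    n_db = int(m.group("db") or 0)
    return Substance(
        id=name,
        name=name,
        chain_length=chain,
        n_methyl=n_methyl,
        n_double_bonds=n_db,
        klass=infer_class(n_methyl, n_db),
    )


def kovats_index(rt: float, alkane_ladder: Sequence[tuple[int, float]]) -> float:
    """Linear (van den Dool-Kratz) retention index for a temperature-programmed run.

    ``alkane_ladder`` is a sequence of ``(carbon_number, retention_time)``
    pairs for the n-alkane standards; RI = 100*(n + (rt-rt_n)/(rt_{n+1}-rt_n)).
    """
    ladder = sorted(alkane_ladder, key=lambda p: p[0])
    rts = [p[1] for p in ladder]
    if len(ladder) < 2:
        raise ValueError("alkane ladder needs at least two standards")
    if any(b <= a for a, b in zip(rts, rts[1:])):
        raise ValueError("alkane ladder retention times must be strictly increasing")
    if not (rts[0] <= rt <= rts[-1]):
        raise ValueError(
            f"retention time {rt} outside ladder span [{rts[0]}, {rts[-1]}]"
        )
    for (c0, t0), (c1, t1) in zip(ladder, ladder[1:]):
        if t0 <= rt <= t1:
            return 100.0 * (c0 + (c1 - c0) * (rt - t0) / (t1 - t0))
    raise AssertionError("unreachable")  # pragma: no cover


class PeakTable:
    """Samples x substances abundance matrix with substance annotations.

    ``abundance`` is indexed by sample id with one column per substance id;
    ``samples`` carries optional per-colony metadata (genus, chemotype,
    location, lon/lat) on the same index.
    """

    def __init__(
        self,
        abundance: pd.DataFrame,
        substances: Sequence[Substance],
        samples: pd.DataFrame | None = None,
    ) -> None:
        abundance = abundance.astype(float)
        if abundance.index.duplicated().any():
            dups = abundance.index[abundance.index.duplicated()].tolist()
            raise ValueError(f"duplicated sample ids: {dups}")
        if abundance.columns.duplicated().any():
            dups = abundance.columns[abundance.columns.duplicated()].tolist()
            raise ValueError(f"duplicated substance ids: {dups}")
        sub_ids = [s.id for s in substances]
        if len(set(sub_ids)) != len(sub_ids):
            raise ValueError("duplicated substance annotation ids")
        missing = [c for c in abundance.columns if c not in set(sub_ids)]
        if missing:
            raise ValueError(f"substances without annotation: {missing}")
        extra = [s for s in sub_ids if s not in set(abundance.columns)]
        if extra:
            raise ValueError(f"annotations without abundance column: {extra}")
        neg = np.argwhere(abundance.values < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative abundance at sample {abundance.index[i]!r}, "
                f"substance {abundance.columns[j]!r}"
            )
        # keep annotation order aligned with the columns
        by_id = {s.id: s for s in substances}
        self.substances: list[Substance] = [by_id[c] for c in abundance.columns]
        self.abundance = abundance
        if samples is not None:
            samples = samples.loc[abundance.index]
        self.samples = samples

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def substance_ids(self) -> list[str]:
        return list(self.abundance.columns)

    def substance(self, sid: str) -> Substance:
        return next(s for s in self.substances if s.id == sid)

    # ---- I/O ---------------------------------------------------------
    def write(
        self,
        peaks_csv: str | Path,
        annot_csv: str | Path,
        meta_csv: str | Path | None = None,
    ) -> None:
        self.abundance.to_csv(peaks_csv, index_label="sample")
        pd.DataFrame(
            {
                "id": [s.id for s in self.substances],
                "name": [s.name for s in self.substances],
                "chain_length": [s.chain_length for s in self.substances],
                "n_methyl": [s.n_methyl for s in self.substances],
                "n_double_bonds": [s.n_double_bonds for s in self.substances],
                "class": [s.klass for s in self.substances],
                "rt": [s.retention_time for s in self.substances],
            }
        ).to_csv(annot_csv, index=False)
        if meta_csv is not None and self.samples is not None:
            self.samples.to_csv(meta_csv, index_label="sample")

    @classmethod
    def read(
        cls,
        peaks_csv: str | Path,
        annot_csv: str | Path,
        meta_csv: str | Path | None = None,
    ) -> "PeakTable":
        ab = pd.read_csv(peaks_csv, index_col="sample")
        ann = pd.read_csv(annot_csv)
        subs = [
            Substance(
                id=str(r["id"]),
                name=str(r["name"]),
                chain_length=int(r["chain_length"]),
                n_methyl=int(r["n_methyl"]),
                n_double_bonds=int(r["n_double_bonds"]),
                klass=str(r["class"]),
                retention_time=None if pd.isna(r.get("rt")) else float(r["rt"]),
            )
            for _, r in ann.iterrows()
        ]
        meta = pd.read_csv(meta_csv, index_col="sample") if meta_csv else None
        return cls(ab, subs, meta)


class CompositionMatrix:
    """Row-closed (proportions summing to one) view of a peak table."""

    def __init__(
        self,
        proportions: pd.DataFrame,
        substances: Sequence[Substance],
        samples: pd.DataFrame | None = None,
    ) -> None:
        vals = proportions.values
        if (vals < 0).any() or (vals > 1 + 1e-12).any():
            raise ValueError("proportions must lie in [0, 1]")
        sums = vals.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = proportions.index[np.argmax(np.abs(sums - 1.0))]
            raise ValueError(f"row {bad!r} does not sum to 1")
        self.proportions = proportions
        self.substances = list(substances)
        self.samples = samples

    @property
    def sample_ids(self) -> list[str]:
        return list(self.proportions.index)


def normalize_closure(pt: PeakTable | pd.DataFrame) -> CompositionMatrix:
    """Close each row of a peak table to unit sum."""
    if isinstance(pt, pd.DataFrame):
        ab, subs, meta = pt, None, None
    else:
        ab, subs, meta = pt.abundance, pt.substances, pt.samples
    sums = ab.sum(axis=1)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total abundance")
    props = ab.div(sums, axis=0)
    if subs is None:
        subs = [
            Substance(c, c, 0, 0, 0, "non-hydrocarbon") for c in ab.columns
        ]
    return CompositionMatrix(props, subs, meta)


def filter_substances(
    pt: PeakTable,
    group_labels: pd.Series | Sequence[str],
    min_mean: float = 0.001,
    min_presence: float = 0.20,
) -> tuple[PeakTable, pd.DataFrame]:
    """Apply the CHC inclusion rules within each chemotype group.

    Non-hydrocarbons are always removed. A hydrocarbon is kept if, in at
    least one group, its mean proportion is >= ``min_mean`` and it is present
    in >= ``min_presence`` of that group's samples. Polyunsaturated
    substances (two or more double bonds) failing both thresholds are still
    retained when a retained unsaturated substance (>= 1 double bond) of the
    same chain length exists anywhere in the table.

    Returns the filtered table and a report of dropped substances.
    """
    labels = pd.Series(group_labels, index=pt.abundance.index)
    if labels.isna().any():
        bad = labels.index[labels.isna()].tolist()
        raise ValueError(f"missing group label for samples: {bad}")
    props = normalize_closure(pt).proportions

    keep: dict[str, str] = {}
    drop: dict[str, str] = {}
    for sub in pt.substances:
        if sub.klass == "non-hydrocarbon":
            drop[sub.id] = "non-hydrocarbon"
            continue
        ok = False
        for g, idx in props.groupby(labels).groups.items():
            col = props.loc[idx, sub.id]
            if col.mean() >= min_mean and (col > 0).mean() >= min_presence:
                ok = True
                break
        if ok:
            keep[sub.id] = "passed thresholds"
        else:
            drop[sub.id] = (
                f"mean < {min_mean} or presence < {min_presence} in every group"
            )

    # polyunsaturated exception: rescued if a same-chain unsaturated CHC is kept
    kept_unsat_chains = {
        s.chain_length
        for s in pt.substances
        if s.id in keep and s.n_double_bonds >= 1
    }
    for sub in pt.substances:
        if (
            sub.id in drop
            and sub.klass != "non-hydrocarbon"
            and sub.n_double_bonds >= 2
            and sub.chain_length in kept_unsat_chains
        ):
            keep[sub.id] = "polyunsaturated exception"
            del drop[sub.id]

    if not keep:
        raise ValueError("filtering removed every substance")
    kept_ids = [s.id for s in pt.substances if s.id in keep]
    report = pd.DataFrame(
        {
            "substance": list(drop.keys()),
            "reason": list(drop.values()),
        }
    )
    out = PeakTable(
        pt.abundance[kept_ids],
        [s for s in pt.substances if s.id in keep],
        pt.samples,
    )
    return out, report


@dataclass
class ClassAggregate:
    """Substance-class aggregates of a composition matrix.

    ``per_sample`` has a (class, chain length) MultiIndex on the columns;
    ``class_totals`` sums across chain lengths. Row sums are conserved.
    """

    per_sample: pd.DataFrame
    class_totals: pd.DataFrame

    def group_means(self, group_labels: pd.Series | Sequence[str]) -> pd.DataFrame:
        labels = pd.Series(group_labels, index=self.per_sample.index)
        return self.per_sample.groupby(labels).mean()


def aggregate_by_class(cm: CompositionMatrix) -> ClassAggregate:
    """Pool proportions per (substance class, chain length) and per class."""
    cols = pd.MultiIndex.from_tuples(
        [(s.klass, s.chain_length) for s in cm.substances],
        names=["class", "chain_length"],
    )
    wide = pd.DataFrame(cm.proportions.values, index=cm.proportions.index, columns=cols)
    per_sample = wide.T.groupby(level=["class", "chain_length"]).sum().T
    class_totals = per_sample.T.groupby(level="class").sum().T
    return ClassAggregate(per_sample=per_sample, class_totals=class_totals)
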