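"""Data model, validation and I/O for half-diallel split-plot trials.

A trial crosses ``n`` inbred parents in all n(n-1)/2 unordered combinations
(no selfs, no reciprocals) and evaluates the F1 hybrids in a split-plot
randomized-complete-block layout: plant densities on main plots, hybrids on
sub-plots, replicated within each location.

The canonical in-memory container for plot-level data is a tidy pandas
DataFrame with one row per plot per trait and columns::

    location, rep, density, parent1, parent2, trait, value

Check (non-diallel) hybrids are carried with ``parent1`` set to the check
code and an empty ``parent2``; they never enter the diallel arithmetic.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRAIT_UNITS",
    "TRAITS",
    "COLUMNS",
    "SchemaError",
    "ParseError",
    "PlotObservation",
    "TrialDesign",
    "CrossMeanMatrix",
    "ValidationReport",
    "cross_id",
    "entry_label",
    "observations_to_frame",
    "frame_to_observations",
    "load_trial",
    "write_trial",
    "validate_design",
    "cross_means",
]

#: Closed trait vocabulary with measurement units.
TRAIT_UNITS: dict[str, str] = {
    "DTS": "days",      # days to 50% silking
    "ASI": "days",      # anthesis-silking interval
    "PLHT": "cm",       # plant height
    "EHT": "cm",        # ear height
    "LANG": "degrees",  # leaf angle above the ear
    "CHLC": "SPAD",     # chlorophyll content
    "ED": "cm",         # ear diameter
    "NRPE": "count",    # number of rows per ear
    "NKPR": "count",    # number of kernels per row
    "TKW": "g",         # thousand-kernel weight
    "GYPP": "g",        # grain yield per plant
    "GYPH": "t/ha",     # grain yield per hectare
}
TRAITS: tuple[str, ...] = tuple(TRAIT_UNITS)

#: Traits that are counts or yields and must be non-negative.
_NONNEGATIVE = frozenset({"NRPE", "NKPR", "TKW", "GYPP", "GYPH"})

COLUMNS = ("location", "rep", "density", "parent1", "parent2", "trait", "value")


class SchemaError(ValueError):
    """An input table is missing a required column."""


class ParseError(ValueError):
    """A row of an input table cannot be interpreted."""


def cross_id(p1: str, p2: str) -> tuple[str, str]:
    """Canonical identity of a cross: the sorted parent pair."""
    if p1 == p2:
        raise ValueError(f"self-cross {p1!r} x {p2!r} is not a valid half-diallel entry")
    return (p1, p2) if p1 < p2 else (p2, p1)


def entry_label(p1: str, p2) -> str:
    """Human-readable entry code: 'L1xL2' for crosses, the code itself for checks."""
    if p2 is None or (isinstance(p2, float) and np.isnan(p2)) or p2 == "":
        return str(p1)
    a, b = cross_id(str(p1), str(p2))
    return f"{a}x{b}"


class PlotObservation(NamedTuple):
    """One plot-level measurement of one trait."""

    location: str
    rep: int
    density: str
    parent1: str
    parent2: str | None  # None for check entries
    trait: str
    value: float


@dataclass(frozen=True)
class TrialDesign:
    """Skeleton of a half-diallel x split-plot trial.

    Parameters
    ----------
    parents
        Ordered parent codes (n of them).
    crosses
        Unordered parent pairs, stored sorted; complete half-diallels carry
        exactly n(n-1)/2 of them and never a self-pair.
    locations, densities
        Location codes and density labels; densities are ordered from
        thinnest to densest planting.
    reps
        Replicates per location.
    plants_per_ha
        Optional plant population for each density label; must be strictly
        increasing along ``densities``.
    check_entries
        Non-diallel check hybrids carried through summaries only.
    """

    parents: tuple[str, ...]
    crosses: tuple[tuple[str, str], ...]
    locations: tuple[str, ...]
    densities: tuple[str, ...]
    reps: int
    plants_per_ha: Mapping[str, float] | None = None
    check_entries: tuple[str, ...] = ()

    def __post_init__(self):
        seen = set()
        for p1, p2 in self.crosses:
            if p1 == p2:
                raise ValueError(f"self-pair ({p1}, {p2}) in crosses")
            if (p1, p2) != cross_id(p1, p2):
                raise ValueError(f"cross ({p1}, {p2}) not stored as sorted pair")
            if (p1, p2) in seen:
                raise ValueError(f"duplicate cross ({p1}, {p2})")
            if p1 not in self.parents or p2 not in self.parents:
                raise ValueError(f"cross ({p1}, {p2}) uses unknown parent")
            seen.add((p1, p2))
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.plants_per_ha is not None:
            levels = [self.plants_per_ha[d] for d in self.densities]
            if any(b <= a for a, b in zip(levels, levels[1:])):
                raise ValueError("densities must be strictly increasing in plants/ha")

    @property
    def n_parents(self) -> int:
        return len(self.parents)

    @property
    def is_complete_diallel(self) -> bool:
        n = self.n_parents
        return len(self.crosses) == n * (n - 1) // 2

    @classmethod
    def complete(
        cls,
        parents: Sequence[str],
        locations: Sequence[str],
        densities: Sequence[str],
        reps: int,
        plants_per_ha: Mapping[str, float] | None = None,
        check_entries: Sequence[str] = (),
    ) -> "TrialDesign":
        """All n(n-1)/2 crosses of ``parents``."""
        crosses = tuple(itertools.combinations(sorted(parents), 2))
        return cls(
            parents=tuple(parents),
            crosses=crosses,
            locations=tuple(locations),
            densities=tuple(densities),
            reps=int(reps),
            plants_per_ha=dict(plants_per_ha) if plants_per_ha else None,
            check_entries=tuple(check_entries),
        )

    @classmethod
    def from_observations(cls, obs: pd.DataFrame) -> "TrialDesign":
        """Infer the design skeleton from an observation table."""
        df = obs
        is_cross = df["parent2"].notna() & (df["parent2"] != "")
        crosses = sorted(
            {cross_id(str(a), str(b)) for a, b in df.loc[is_cross, ["parent1", "parent2"]].itertuples(index=False)}
        )
        parents = tuple(sorted({p for pair in crosses for p in pair}))
        checks = tuple(sorted(set(df.loc[~is_cross, "parent1"].astype(str))))
        return cls(
            parents=parents,
            crosses=tuple(crosses),
            locations=tuple(sorted(df["location"].astype(str).unique())),
            densities=tuple(sorted(df["density"].astype(str).unique())),
            reps=int(df["rep"].max()),
            check_entries=checks,
        )

    def to_json(self, path=None) -> str:
        payload = {
            "parents": list(self.parents),
            "crosses": [list(c) for c in self.crosses],
            "locations": list(self.locations),
            "densities": list(self.densities),
            "reps": self.reps,
            "plants_per_ha": dict(self.plants_per_ha) if self.plants_per_ha else None,
            "check_entries": list(self.check_entries),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "TrialDesign":
        try:
            payload = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            parents=tuple(payload["parents"]),
            crosses=tuple(tuple(c) for c in payload["crosses"]),
            locations=tuple(payload["locations"]),
            densities=tuple(payload["densities"]),
            reps=int(payload["reps"]),
            plants_per_ha=payload.get("plants_per_ha"),
            check_entries=tuple(payload.get("check_entries", ())),
        )


@dataclass
class CrossMeanMatrix:
    """Symmetric n x n table of cross means y_ij for one stratum.

    The diagonal is undefined (no selfs in a half-diallel) and stored as
    NaN. ``r_basis`` is the number of plot observations averaged into each
    cell; the Griffing machinery requires it to be constant across cells.
    """

    parents: tuple[str, ...]
    values: np.ndarray
    stratum: str
    r_basis: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.parents)
        if v.shape != (n, n):
            raise ValueError("means matrix shape does not match parents")
        off = ~np.eye(n, dtype=bool)
        if not np.allclose(v[off], v.T[off], equal_nan=False):
            raise ValueError("cross-mean matrix must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.parents)

    def y(self, p1: str, p2: str) -> float:
        a, b = cross_id(p1, p2)
        i, j = self.parents.index(a), self.parents.index(b)
        return float(self.values[i, j])

    def pair_series(self) -> pd.Series:
        """Upper-triangle means keyed by (parent1, parent2)."""
        idx, vals = [], []
        for i, j in itertools.combinations(range(self.n), 2):
            idx.append(cross_id(self.parents[i], self.parents[j]))
            vals.append(self.values[i, j])
        return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx, names=["parent1", "parent2"]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.parents), columns=list(self.parents))


@dataclass
class ValidationReport:
    """Completeness/balance report for one trial (report, not exception)."""

    balanced: bool
    cell_counts: pd.DataFrame  # columns trait, location, rep, density, entry, count
    missing: list[tuple]       # expected cells with count 0
    duplicated: list[tuple]    # cells with count > 1
    expected_cells_per_trait: int

    def to_json(self, path=None) -> str:
        payload = {
            "balanced": bool(self.balanced),
            "expected_cells_per_trait": self.expected_cells_per_trait,
            "n_missing": len(self.missing),
            "n_duplicated": len(self.duplicated),
            "missing": [list(m) for m in self.missing[:200]],
            "duplicated": [list(m) for m in self.duplicated[:200]],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# conversions and I/O


def observations_to_frame(obs: Iterable[PlotObservation]) -> pd.DataFrame:
    df = pd.DataFrame(list(obs), columns=list(COLUMNS))
    return df


def frame_to_observations(df: pd.DataFrame) -> list[PlotObservation]:
    out = []
    for row in df.itertuples(index=False):
        p2 = row.parent2
        if p2 == "" or (isinstance(p2, float) and np.isnan(p2)):
            p2 = None
        out.append(
            PlotObservation(
                str(row.location), int(row.rep), str(row.density),
                str(row.parent1), p2 if p2 is None else str(p2),
                str(row.trait), float(row.value),
            )
        )
    return out


def _as_frame(obs) -> pd.DataFrame:
    if isinstance(obs, pd.DataFrame):
        return obs
    return observations_to_frame(obs)


def load_trial(path, schema: Mapping[str, str] | None = None) -> tuple[TrialDesign, pd.DataFrame]:
    """Read a tidy observation CSV and infer the design.

    ``schema`` maps canonical column names to the file's column names, e.g.
    ``{"location": "site"}``. Unknown trait codes and self-cross rows are
    rejected; non-numeric values raise :class:`ParseError` with the row
    index.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    schema = dict(schema or {})
    rename = {schema.get(c, c): c for c in COLUMNS}
    missing = [schema.get(c, c) for c in COLUMNS if schema.get(c, c) not in raw.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")
    df = raw.rename(columns=rename)[list(COLUMNS)].copy()

    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() & (df["value"] != "")
    if bad.any():
        i = int(bad.idxmax())
        raise ParseError(f"non-numeric value {df.loc[i, 'value']!r} at row {i}")
    if values.isna().any():
        i = int(values.isna().idxmax())
        raise ParseError(f"empty value at row {i}")
    df["value"] = values.astype(float)
    try:
        df["rep"] = df["rep"].astype(int)
    except ValueError as exc:
        raise ParseError(f"non-integer replicate: {exc}") from exc

    unknown = set(df["trait"]) - set(TRAITS)
    if unknown:
        raise ParseError(f"unknown trait code(s): {sorted(unknown)}")
    is_cross = df["parent2"] != ""
    selfed = is_cross & (df["parent1"] == df["parent2"])
    if selfed.any():
        i = int(selfed.idxmax())
        raise ParseError(f"self-cross row at index {i}: {df.loc[i, 'parent1']!r}")
    neg = df["trait"].isin(_NONNEGATIVE) & (df["value"] < 0)
    if neg.any():
        i = int(neg.idxmax())
        raise ParseError(f"negative value for count/yield trait at row {i}")
    if not np.isfinite(df["value"]).all():
        raise ParseError("non-finite trait value")

    # normalize cross orientation to the sorted pair
    swap = is_cross & (df["parent1"] > df["parent2"])
    df.loc[swap, ["parent1", "parent2"]] = df.loc[swap, ["parent2", "parent1"]].values
    design = TrialDesign.from_observations(df)
    return design, df


def write_trial(obs, path) -> None:
    """Write observations as the canonical UTF-8 CSV."""
    _as_frame(obs).to_csv(path, index=False)


def validate_design(design: TrialDesign, obs) -> ValidationReport:
    """Check that every cross x location x density x rep cell is present
    exactly once per trait (checks validated the same way)."""
    df = _as_frame(obs)
    df = df.assign(entry=[entry_label(a, b) for a, b in zip(df["parent1"], df["parent2"])])
    counts = (
        df.groupby(["trait", "location", "rep", "density", "entry"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    entries = [f"{a}x{b}" for a, b in design.crosses] + list(design.check_entries)
    traits = sorted(df["trait"].unique())
    expected = pd.MultiIndex.from_product(
        [traits, design.locations, range(1, design.reps + 1), design.densities, entries],
        names=["trait", "location", "rep", "density", "entry"],
    )
    full = counts.set_index(["trait", "location", "rep", "density", "entry"])["count"].reindex(expected, fill_value=0)
    missing = [tuple(ix) for ix in full.index[full == 0]]
    # cells observed but not expected also break balance
    observed = counts.set_index(["trait", "location", "rep", "density", "entry"]).index
    unexpected = [tuple(ix) for ix in observed.difference(expected)]
    duplicated = [tuple(ix) for ix in full.index[full > 1]] + [
        tuple(ix) for ix in observed if tuple(ix) in set(unexpected)
    ]
    balanced = not missing and not unexpected and bool((full == 1).all())
    return ValidationReport(
        balanced=balanced,
        cell_counts=full.reset_index(),
        missing=missing,
        duplicated=[tuple(ix) for ix in full.index[full > 1]] + unexpected,
        expected_cells_per_trait=len(entries) * len(design.locations) * len(design.densities) * design.reps,
    )


def cross_means(
    obs,
    trait: str,
    design: TrialDesign | None = None,
    density: str | None = None,
    location: str | None = None,
) -> CrossMeanMatrix:
    """Average plot values per cross within a stratum.

    The stratum is the subset selected by ``density``/``location``; the
    factors left unspecified are averaged over. Cells must be balanced:
    every cross must contribute the same number of plots (``r_basis``).
    """
    df = _as_frame(obs)
    df = df[(df["trait"] == trait) & (df["parent2"] != "") & df["parent2"].notna()]
    label = [trait]
    if density is not None:
        df = df[df["density"] == density]
        label.append(str(density))
    if location is not None:
        df = df[df["location"] == location]
        label.append(str(location))
    if df.empty:
        raise ValueError(f"no observations for trait {trait!r} in stratum {label}")

    grouped = df.groupby(["parent1", "parent2"])["value"]
    counts = grouped.size()
    if counts.nunique() != 1:
        off = counts[counts != counts.mode().iloc[0]]
        raise ValueError(f"unbalanced cells for crosses: {list(off.index)}")
    means = grouped.mean()

    if design is not None:
        parents = design.parents
        expected = set(design.crosses)
        got = set(means.index)
        if expected - got:
            raise ValueError(f"missing crosses in stratum: {sorted(expected - got)}")
    else:
        parents = tuple(sorted({p for pair in means.index for p in pair}))
    n = len(parents)
    mat = np.full((n, n), np.nan)
    pos = {p: i for i, p in enumerate(parents)}
    for (p1, p2), v in means.items():
        i, j = pos[p1], pos[p2]
        mat[i, j] = mat[j, i] = v
    return CrossMeanMatrix(
        parents=parents, values=mat, stratum=" / ".join(label), r_basis=int(counts.iloc[0])
    )
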