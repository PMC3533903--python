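"""Item specifications and response-matrix recoding for polytomous questionnaires.

A questionnaire dimension is a set of ordinal items scored ``0..m_j``.  This
module holds the data model (:class:`ItemSpec`, :class:`ResponseMatrix`,
:class:`DIFSpec`) and the three recoding steps applied before any model is
fitted:

* reversal of negatively worded items (``y -> m_j - y``),
* aggregation of locally dependent items into sum-scored super-items,
* expansion of items with differential functioning (DIF) into group-specific
  pseudo-items.

A pseudo-item is a copy of an item restricted to one covariate group: it takes
the original response for persons in the group and is missing for everyone
else, so that group-specific thresholds can be estimated inside one model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ItemSpec",
    "ResponseMatrix",
    "DIFSpec",
    "reverse_code",
    "build_super_items",
    "expand_pseudo_items",
]


@dataclass(frozen=True)
class ItemSpec:
    """Specification of one ordinal item.

    Parameters
    ----------
    item_id : str
        Unique item label.
    n_categories : int
        Number of response categories (>= 2); the maximal code is
        ``m = n_categories - 1``.
    reverse : bool
        Whether the raw coding must be reflected (``y -> m - y``) so that
        higher codes mean more of the trait.
    parent_ids : tuple of str
        Source items when this item is a sum-scored super-item; empty
        otherwise.
    """

    item_id: str
    n_categories: int
    reverse: bool = False
    parent_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError(
                f"item {self.item_id!r}: n_categories must be >= 2, "
                f"got {self.n_categories}"
            )

    @property
    def m(self) -> int:
        """Maximal category code (number of item steps)."""
        return self.n_categories - 1


@dataclass
class ResponseMatrix:
    """N x J matrix of ordinal response codes with missing entries.

    ``values`` is a float array; missing responses are ``NaN`` and observed
    responses are integer-valued codes in ``0..m_j``.
    """

    values: np.ndarray
    person_ids: np.ndarray
    item_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.person_ids = np.asarray(self.person_ids)
        self.item_ids = list(self.item_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d array")
        n, j = self.values.shape
        if len(self.person_ids) != n:
            raise ValueError("person_ids length does not match values")
        if len(self.item_ids) != j:
            raise ValueError("item_ids length does not match values")
        if len(set(self.item_ids)) != j:
            raise ValueError("item_ids must be unique")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def column(self, item_id: str) -> np.ndarray:
        return self.values[:, self.item_ids.index(item_id)]

    def observed(self) -> np.ndarray:
        """Boolean mask of observed (non-missing) cells."""
        return ~np.isnan(self.values)

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(self.values.copy(), self.person_ids.copy(),
                              list(self.item_ids))

    # -- validation --------------------------------------------------------
    def validate(self, items: list[ItemSpec]) -> None:
        """Check every observed code against its item's category range."""
        spec = {s.item_id: s for s in items}
        for j, iid in enumerate(self.item_ids):
            if iid not in spec:
                raise ValueError(f"no ItemSpec for item {iid!r}")
            col = self.values[:, j]
            obs = ~np.isnan(col)
            bad = obs & ((col < 0) | (col > spec[iid].m) | (col != np.round(col)))
            if bad.any():
                n0 = self.person_ids[np.nonzero(bad)[0][0]]
                raise ValueError(
                    f"item {iid!r}: code {col[bad][0]} out of range 0..{spec[iid].m} "
                    f"(first offending person {n0!r})"
                )

    def drop_empty_persons(self) -> "ResponseMatrix":
        """Drop persons with no observed response at all."""
        keep = self.observed().any(axis=1)
        return ResponseMatrix(self.values[keep], self.person_ids[keep],
                              list(self.item_ids))

    # -- I/O ---------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.item_ids)
        df.insert(0, "person_id", self.person_ids)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ResponseMatrix":
        if "person_id" in df.columns:
            pid = df["person_id"].to_numpy()
            vals = df.drop(columns="person_id")
        else:
            pid = df.index.to_numpy()
            vals = df
        return cls(vals.to_numpy(dtype=float), pid, list(vals.columns))


@dataclass
class DIFSpec:
    """Which items are split into pseudo-items, per covariate factor.

    ``splits`` maps item id to a list of ``(factor, grouping)`` pairs; a
    grouping is a list of level groups (each a list of levels) that must
    partition the factor's observed levels.  An item may be split on more than
    one factor.
    """

    splits: dict[str, list[tuple[str, list[list[str]]]]] = field(default_factory=dict)

    def __bool__(self) -> bool:
        return bool(self.splits)

    def validate_partition(self, factor_levels: dict[str, set]) -> None:
        for item, pairs in self.splits.items():
            for factor, grouping in pairs:
                flat = [lv for grp in grouping for lv in grp]
                if len(flat) != len(set(flat)):
                    raise ValueError(
                        f"{item}/{factor}: level appears in more than one group")
                if set(map(str, flat)) != {str(x) for x in factor_levels[factor]}:
                    raise ValueError(
                        f"{item}/{factor}: grouping does not partition the "
                        f"levels {sorted(map(str, factor_levels[factor]))}")


# ---------------------------------------------------------------------------
# recoding operations
# ---------------------------------------------------------------------------

def reverse_code(matrix: ResponseMatrix, items: list[ItemSpec]) -> ResponseMatrix:
    """Reflect the codes of items flagged ``reverse`` (``y -> m_j - y``).

    Missing stays missing; non-flagged items are untouched.  Codes outside the
    item's range are rejected.
    """
    matrix.validate(items)
    out = matrix.copy()
    for spec in items:
        if spec.reverse and spec.item_id in out.item_ids:
            j = out.item_ids.index(spec.item_id)
            out.values[:, j] = spec.m - out.values[:, j]
    return out


def _super_item_id(parent_ids: list[str]) -> str:
    """PF1 + PF2 -> PF12 when the parents share an alphabetic stem."""
    stems, tails = [], []
    for pid in parent_ids:
        m = re.fullmatch(r"([A-Za-z_]+)(\d+)", pid)
        if m is None:
            return "+".join(parent_ids)
        stems.append(m.group(1))
        tails.append(m.group(2))
    if len(set(stems)) == 1:
        return stems[0] + "".join(tails)
    return "+".join(parent_ids)


def build_super_items(
    matrix: ResponseMatrix,
    items: list[ItemSpec],
    groups: list[list[str]],
) -> tuple[ResponseMatrix, list[ItemSpec]]:
    """Replace each group of locally dependent items by a sum-scored super-item.

    The super-item code is the plain sum of the component codes, on
    ``0..sum(m_parent)``; it is missing whenever ANY component is missing (the
    sum is undefined otherwise and the full range is preserved).  Groups must
    not overlap.  Returns the recoded matrix and the full post-recoding item
    spec list (super-items in place of their first parent, other items
    unchanged, in matrix column order).
    """
    matrix.validate(items)
    spec = {s.item_id: s for s in items}
    flat = [iid for g in groups for iid in g]
    if len(flat) != len(set(flat)):
        raise ValueError("super-item groups overlap")
    for iid in flat:
        if iid not in matrix.item_ids:
            raise ValueError(f"grouped item {iid!r} not in matrix")

    group_of = {iid: tuple(g) for g in groups for iid in g}
    new_cols: list[np.ndarray] = []
    new_specs: list[ItemSpec] = []
    emitted: set[tuple[str, ...]] = set()
    for iid in matrix.item_ids:
        g = group_of.get(iid)
        if g is None:
            new_cols.append(matrix.column(iid).copy())
            new_specs.append(spec[iid])
        elif g not in emitted:  # super-item sits at its first parent's column
            cols = np.stack([matrix.column(p) for p in g], axis=1)
            new_cols.append(cols.sum(axis=1))  # NaN if any component missing
            new_specs.append(ItemSpec(
                item_id=_super_item_id(list(g)),
                n_categories=1 + sum(spec[p].m for p in g),
                parent_ids=g,
            ))
            emitted.add(g)
    out = ResponseMatrix(np.stack(new_cols, axis=1), matrix.person_ids.copy(),
                         [s.item_id for s in new_specs])
    return out, new_specs


def pseudo_item_id(item_id: str, factor: str, group: list) -> str:
    return f"{item_id}@{factor}:" + "+".join(str(lv) for lv in group)


def expand_pseudo_items(
    matrix: ResponseMatrix,
    covariates: pd.DataFrame,
    dif: DIFSpec,
    items: list[ItemSpec] | None = None,
    cross_product: bool = False,
) -> tuple[ResponseMatrix, list[ItemSpec]]:
    """Replace DIF items by per-group pseudo-items.

    Each split item is replaced by one pseudo-item per level group: the
    pseudo-item equals the original response for persons in the group and is
    missing for everyone else.  With the default per-factor splitting an item
    flagged on two factors yields one independent pseudo-item set per factor;
    with ``cross_product=True`` it yields one pseudo-item per cell of the
    cross-classification, so each response appears exactly once.

    ``covariates`` must be aligned with the matrix rows (same order) and carry
    every factor named in ``dif``.
    """
    if items is None:
        obs_max = np.nanmax(matrix.values, axis=0)
        items = [ItemSpec(iid, int(mx) + 1 if np.isfinite(mx) else 2)
                 for iid, mx in zip(matrix.item_ids, obs_max)]
    spec = {s.item_id: s for s in items}
    if not dif:
        return matrix, [spec[iid] for iid in matrix.item_ids]

    if len(covariates) != matrix.n_persons:
        raise ValueError("covariate table not aligned with response matrix")
    factor_levels = {f: set(covariates[f].astype(str).unique())
                     for pairs in dif.splits.values() for f, _ in pairs}
    dif.validate_partition(factor_levels)

    def group_masks(pairs):
        """Yield (suffix-id parts, person mask) per pseudo-item of one item."""
        if cross_product and len(pairs) > 1:
            def rec(i):
                if i == len(pairs):
                    yield [], np.ones(matrix.n_persons, dtype=bool)
                    return
                factor, grouping = pairs[i]
                lv = covariates[factor].astype(str).to_numpy()
                for grp in grouping:
                    m = np.isin(lv, [str(x) for x in grp])
                    for parts, rest in rec(i + 1):
                        yield [(factor, grp)] + parts, m & rest
            yield from rec(0)
        else:
            for factor, grouping in pairs:
                lv = covariates[factor].astype(str).to_numpy()
                for grp in grouping:
                    yield [(factor, grp)], np.isin(lv, [str(x) for x in grp])

    new_cols, new_specs = [], []
    for iid in matrix.item_ids:
        base = spec[iid]
        if iid not in dif.splits:
            new_cols.append(matrix.column(iid).copy())
            new_specs.append(base)
            continue
        col = matrix.column(iid)
        for parts, mask in group_masks(dif.splits[iid]):
            pseudo = np.full_like(col, np.nan)
            pseudo[mask] = col[mask]
            pid = iid + "".join(f"@{f}:" + "+".join(map(str, g)) for f, g in parts)
            new_cols.append(pseudo)
            new_specs.append(replace(base, item_id=pid, reverse=False))
    out = ResponseMatrix(np.stack(new_cols, axis=1), matrix.person_ids.copy(),
                         [s.item_id for s in new_specs])
    return out, new_specs
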