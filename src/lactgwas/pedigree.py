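"""Pedigree handling: sorting, inbreeding, and the numerator relationship matrix.

The additive (numerator) relationship matrix A holds expected additive genetic
relationships between animals derived from a sire–dam pedigree; its diagonal is
1 + F, with F the inbreeding coefficient (half the additive relationship between
an animal's parents).  A sparse inverse is built directly from the pedigree with
Henderson's rules, using inbreeding-corrected Mendelian sampling variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = 0


@dataclass
class Pedigree:
    """Topologically sorted pedigree (parents precede offspring).

    entries: DataFrame with columns animal_id, sire_id, dam_id, birth_year;
    unknown parents are encoded as 0.
    """

    entries: pd.DataFrame
    index: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {a: i for i, a in enumerate(self.entries["animal_id"])}
        self._validate_sorted()

    def _validate_sorted(self) -> None:
        for row in self.entries.itertuples(index=False):
            i = self.index[row.animal_id]
            for p in (row.sire_id, row.dam_id):
                if p != UNKNOWN and self.index.get(p, -1) >= i:
                    raise ValueError(
                        f"pedigree not sorted: parent {p} does not precede {row.animal_id}"
                    )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def animal_ids(self) -> np.ndarray:
        return self.entries["animal_id"].to_numpy()

    def parent_indices(self) -> np.ndarray:
        """(n, 2) array of sire/dam positions, -1 for unknown."""
        n = len(self)
        out = np.full((n, 2), -1, dtype=np.int64)
        for i, row in enumerate(self.entries.itertuples(index=False)):
            if row.sire_id != UNKNOWN:
                out[i, 0] = self.index[row.sire_id]
            if row.dam_id != UNKNOWN:
                out[i, 1] = self.index[row.dam_id]
        return out

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        df = pd.read_csv(path)
        return trace_and_sort(df)


@dataclass
class RelationshipMatrix:
    """Symmetric matrix of additive relationships; diagonal 1 + F."""

    animal_ids: np.ndarray
    values: np.ndarray

    @property
    def dimension(self) -> int:
        return self.values.shape[0]


def trace_and_sort(raw: pd.DataFrame) -> Pedigree:
    """Complete and topologically sort raw pedigree entries.

    Parents referenced but absent from the list are inserted as founders.
    Raises on cycles (an animal its own ancestor), listing the cycle.
    """
    df = raw.copy()
    if "birth_year" not in df.columns:
        df["birth_year"] = 0
    df["sire_id"] = df["sire_id"].fillna(UNKNOWN)
    df["dam_id"] = df["dam_id"].fillna(UNKNOWN)
    ids = set(df["animal_id"])
    if len(ids) != len(df):
        raise ValueError("duplicate animal ids in pedigree")
    # insert missing parents as founders
    missing = []
    for col in ("sire_id", "dam_id"):
        for p in df[col]:
            if p != UNKNOWN and p not in ids:
                ids.add(p)
                missing.append(p)
    if missing:
        founders = pd.DataFrame(
            {
                "animal_id": missing,
                "sire_id": UNKNOWN,
                "dam_id": UNKNOWN,
                "birth_year": 0,
            }
        )
        df = pd.concat([founders, df], ignore_index=True)

    import networkx as nx

    G = nx.DiGraph()
    pos = {a: i for i, a in enumerate(df["animal_id"])}
    G.add_nodes_from(df["animal_id"])
    for r in df.itertuples(index=False):
        for p in (r.sire_id, r.dam_id):
            if p != UNKNOWN:
                G.add_edge(p, r.animal_id)
    try:
        order = list(nx.lexicographical_topological_sort(G, key=pos.get))
    except nx.NetworkXUnfeasible:
        cycle = [u for u, _ in nx.find_cycle(G)]
        raise ValueError(f"pedigree cycle detected: {cycle}") from None

    df = df.set_index("animal_id").loc[order].reset_index()
    return Pedigree(df[["animal_id", "sire_id", "dam_id", "birth_year"]])


def nrm(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a_ii = 1 + a(sire,dam)/2; a_ij = (a(j,sire_i) + a(j,dam_i))/2 for j < i;
    unknown parents contribute 0.
    """
    n = len(ped)
    par = ped.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = par[i]
        asd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
        if i == 0:
            continue
        contrib = np.zeros(i)
        if s >= 0:
            contrib += A[:i, s]
        if d >= 0:
            contrib += A[:i, d]
        A[:i, i] = A[i, :i] = 0.5 * contrib
    return RelationshipMatrix(ped.animal_ids.copy(), A)


def _ancestor_subpedigree(ped: Pedigree, animal_idx: int, max_generations: int):
    """Indices of `animal_idx` plus its ancestors up to depth max_generations.

    Parents of the animal are depth 1.  Returns (kept indices set, truncated
    parent links): ancestors at the cap keep their row but lose their parents,
    so relationships among them are treated as 0.
    """
    par = ped.parent_indices()
    depth = {animal_idx: 0}
    frontier = [animal_idx]
    for g in range(max_generations):
        nxt = []
        for i in frontier:
            for p in par[i]:
                if p >= 0 and p not in depth:
                    depth[p] = g + 1
                    nxt.append(p)
        frontier = nxt
    keep = sorted(depth)
    links = {}
    for i in keep:
        if depth[i] >= max_generations:
            links[i] = (-1, -1)  # truncated founder
        else:
            links[i] = tuple(p if (p >= 0 and p in depth) else -1 for p in par[i])
    return keep, links


def inbreeding(ped: Pedigree, max_generations: int | None = None) -> pd.Series:
    """Per-animal inbreeding coefficients F_i = a(sire, dam)/2.

    With ``max_generations=None`` the exact coefficients are computed from the
    full pedigree (tabular recursion).  With a finite cap each animal's F is
    computed on its own ancestor sub-pedigree truncated at that depth —
    ancestors at the cap are treated as unrelated non-inbred founders.
    """
    n = len(ped)
    par = ped.parent_indices()
    if max_generations is None:
        A = nrm(ped).values
        F = np.array(
            [
                0.5 * A[par[i, 0], par[i, 1]]
                if par[i, 0] >= 0 and par[i, 1] >= 0
                else 0.0
                for i in range(n)
            ]
        )
    else:
        F = np.zeros(n)
        for i in range(n):
            s, d = par[i]
            if s < 0 or d < 0:
                continue
            keep, links = _ancestor_subpedigree(ped, i, max_generations)
            pos = {orig: k for k, orig in enumerate(keep)}
            m = len(keep)
            Asub = np.zeros((m, m))
            for orig in keep:  # keep is sorted => parents-before-offspring
                k = pos[orig]
                ls, ld = links[orig]
                ks = pos.get(ls, -1) if ls >= 0 else -1
                kd = pos.get(ld, -1) if ld >= 0 else -1
                asd = Asub[ks, kd] if (ks >= 0 and kd >= 0) else 0.0
                Asub[k, k] = 1.0 + 0.5 * asd
                contrib = np.zeros(k)
                if ks >= 0:
                    contrib += Asub[:k, ks]
                if kd >= 0:
                    contrib += Asub[:k, kd]
                Asub[:k, k] = Asub[k, :k] = 0.5 * contrib
            F[i] = 0.5 * Asub[pos[s], pos[d]]
    return pd.Series(F, index=ped.animal_ids, name="F")


def nrm_inverse(ped: Pedigree, with_inbreeding: bool = True):
    """Sparse A^-1 by Henderson's rules.

    The Mendelian sampling variance of animal i is
    d_i = 0.5 - 0.25 (F_s + F_d) with known parents (adjusted for fewer known
    parents); with ``with_inbreeding=False`` parental F are taken as 0.
    Returns a scipy.sparse CSC matrix.
    """
    from scipy import sparse

    n = len(ped)
    par = ped.parent_indices()
    F = inbreeding(ped).to_numpy() if with_inbreeding else np.zeros(n)
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        s, d = par[i]
        fs = F[s] if s >= 0 else 0.0
        fd = F[d] if d >= 0 else 0.0
        if s >= 0 and d >= 0:
            dvar = 0.5 - 0.25 * (fs + fd)
        elif s >= 0 or d >= 0:
            fk = fs if s >= 0 else fd
            dvar = 0.75 - 0.25 * fk
        else:
            dvar = 1.0
        w = 1.0 / dvar
        add(i, i, w)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * w)
                add(p, i, -0.5 * w)
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    add(p, q, 0.25 * w)
    return sparse.csc_matrix(
        sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
    )
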