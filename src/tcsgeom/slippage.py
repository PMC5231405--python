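"""Two-regime superposition matrices quantifying interface "slippage".

For every ordered pair of HK:RR complexes two superpositions are computed:

* **DHp regime** (lower triangle of the printed layout): the structurally
  invariant RR-binding region of the kinase DHp bundle is fitted
  (Cα, residues 190–234 by default) and the rmsd is then *evaluated*, with
  that same transform, over the receiver-domain Cα atoms (residues 1–129).
* **REC regime** (upper triangle): the receiver domains themselves are
  fitted and the rmsd read from the fit.

A rigid, well-packed interface gives similar numbers in both regimes.  A
"slippery" interface — partners sliding against each other while each stays
internally rigid — gives near-zero REC-regime cells but large DHp-regime
cells.  The evaluation rmsd deliberately re-uses the DHp-fit transform
without refitting; refitting (the default in many toolkits) would erase the
contrast this matrix exists to measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tcsgeom.structure import Selection, Structure
from tcsgeom.superpose import kabsch_fit

__all__ = ["ComplexEntry", "SlippageMatrix", "superposition_matrix",
           "slippage_summary", "matrix_from_values"]

DHP_RANGE_DEFAULT = (190, 234)
REC_RANGE_DEFAULT = (1, 129)


@dataclass
class ComplexEntry:
    """One independently refined HK:RR pair entering the matrix.

    ``hk_chains`` lists the kinase chain(s) carrying the DHp fitting region
    (one chain, or both chains of the dimer); ``rr_chain`` is the receiver
    domain evaluated in every cell.
    """

    label: str
    structure: Structure
    hk_chains: tuple[str, ...]
    rr_chain: str
    dhp_range: tuple[int, int] = DHP_RANGE_DEFAULT
    rec_range: tuple[int, int] = REC_RANGE_DEFAULT

    def __post_init__(self):
        if isinstance(self.hk_chains, str):
            self.hk_chains = (self.hk_chains,)
        self.hk_chains = tuple(self.hk_chains)
        present = set(self.structure.chains())
        missing = (set(self.hk_chains) | {self.rr_chain}) - present
        if missing:
            raise ValueError(f"{self.label}: chains {sorted(missing)} not in structure")


@dataclass
class SlippageMatrix:
    """Pairwise rmsd matrices of the two superposition regimes.

    ``m_dhp[i, j]``: REC-Cα rmsd between entries i and j after fitting the
    DHp region; ``m_rec[i, j]``: REC-Cα rmsd after fitting the REC domains
    directly.  Diagonals are zero and both matrices are symmetric.
    """

    labels: list[str]
    m_dhp: np.ndarray
    m_rec: np.ndarray
    n_pairs_dhp: np.ndarray | None = None
    n_pairs_rec: np.ndarray | None = None
    regime_violations: list[tuple[str, str]] = field(default_factory=list)

    def to_layout_frame(self) -> pd.DataFrame:
        """Single square table: DHp regime below the diagonal, REC above."""
        n = len(self.labels)
        m = np.where(np.tri(n, k=-1, dtype=bool), self.m_dhp, self.m_rec)
        np.fill_diagonal(m, 0.0)
        return pd.DataFrame(m, index=self.labels, columns=self.labels)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({"a": self.labels[i], "b": self.labels[j],
                             "rmsd_dhp_fit": self.m_dhp[i, j],
                             "rmsd_rec_fit": self.m_rec[i, j]})
        return pd.DataFrame(rows)


def _rec_selection(entry: ComplexEntry) -> Selection:
    return Selection.make(chains=[entry.rr_chain], res_ranges=[entry.rec_range],
                          atom_names=["CA"])


def _dhp_selection(entry: ComplexEntry) -> Selection:
    return Selection.make(chains=list(entry.hk_chains),
                          res_ranges=[entry.dhp_range], atom_names=["CA"])


def _chain_map(a: ComplexEntry, b: ComplexEntry) -> dict[str, str]:
    m = {ca: cb for ca, cb in zip(a.hk_chains, b.hk_chains)}
    m[a.rr_chain] = b.rr_chain
    return m


def superposition_matrix(entries: list[ComplexEntry]) -> SlippageMatrix:
    """Assemble the two-regime rmsd matrix over all entry pairs.

    Residues missing from any entry are removed from the fitting/evaluation
    sets of *all* entries (common-residue restriction), so every cell is
    computed over the same atom count and cells stay comparable.
    Per-pair superposition failures are raised with the offending labels.
    """
    if len(entries) < 2:
        raise ValueError("need at least two complexes")
    entries = _restrict_to_common_residues(entries)
    n = len(entries)
    m_dhp = np.zeros((n, n))
    m_rec = np.zeros((n, n))
    np_dhp = np.zeros((n, n), dtype=int)
    np_rec = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = entries[i], entries[j]
            cmap = _chain_map(a, b)
            try:
                dhp = kabsch_fit(a.structure, b.structure,
                                 fit_sel=_dhp_selection(a),
                                 eval_sel=_rec_selection(a), chain_map=cmap)
                rec = kabsch_fit(a.structure, b.structure,
                                 fit_sel=_rec_selection(a), chain_map=cmap)
            except Exception as exc:
                raise RuntimeError(
                    f"superposition failed for pair ({a.label}, {b.label}): {exc}"
                ) from exc
            m_dhp[i, j] = m_dhp[j, i] = dhp.rmsd_eval
            m_rec[i, j] = m_rec[j, i] = rec.rmsd_fit
            np_dhp[i, j] = np_dhp[j, i] = dhp.n_eval_pairs
            np_rec[i, j] = np_rec[j, i] = rec.n_pairs
    violations = [(entries[i].label, entries[j].label)
                  for i in range(n) for j in range(i + 1, n)
                  if m_dhp[i, j] < m_rec[i, j] - 1e-9]
    return SlippageMatrix([e.label for e in entries], m_dhp, m_rec,
                          np_dhp, np_rec, violations)


def _restrict_to_common_residues(entries: list[ComplexEntry]) -> list[ComplexEntry]:
    """Drop DHp/REC Cα atoms whose residue number is absent from any entry,
    so all cells are computed over identical residue sets."""
    def rec_resnums(e: ComplexEntry) -> set[int]:
        lo, hi = e.rec_range
        return {a.res_num for a in e.structure.atoms
                if a.chain_id == e.rr_chain and lo <= a.res_num <= hi
                and a.name == "CA"}

    def dhp_resnums(e: ComplexEntry, k: int) -> set[int]:
        lo, hi = e.dhp_range
        return {a.res_num for a in e.structure.atoms
                if a.chain_id == e.hk_chains[k] and lo <= a.res_num <= hi
                and a.name == "CA"}

    n_hk = min(len(e.hk_chains) for e in entries)
    common_rec = set.intersection(*(rec_resnums(e) for e in entries))
    common_dhp = [set.intersection(*(dhp_resnums(e, k) for e in entries))
                  for k in range(n_hk)]
    out = []
    for e in entries:
        keep = []
        for a in e.structure.atoms:
            lo, hi = e.rec_range
            if (a.chain_id == e.rr_chain and a.name == "CA"
                    and lo <= a.res_num <= hi and a.res_num not in common_rec):
                continue
            lo, hi = e.dhp_range
            drop = False
            for k in range(n_hk):
                if (a.chain_id == e.hk_chains[k] and a.name == "CA"
                        and lo <= a.res_num <= hi
                        and a.res_num not in common_dhp[k]):
                    drop = True
                    break
            if not drop:
                keep.append(a)
        s = e.structure.copy()
        s.atoms = keep
        out.append(ComplexEntry(e.label, s, e.hk_chains[:n_hk],
                                e.rr_chain, e.dhp_range, e.rec_range))
    return out


def matrix_from_values(labels: list[str], lower_dhp: np.ndarray,
                       upper_rec: np.ndarray) -> SlippageMatrix:
    """Build a :class:`SlippageMatrix` from already-tabulated rmsd values
    (lower triangle = DHp-fit regime, upper triangle = REC-fit regime)."""
    lower_dhp = np.asarray(lower_dhp, dtype=float)
    upper_rec = np.asarray(upper_rec, dtype=float)
    n = len(labels)
    if lower_dhp.shape != (n, n) or upper_rec.shape != (n, n):
        raise ValueError("matrices must be square and match the label count")
    tri = np.tri(n, k=-1, dtype=bool)
    m_dhp = np.where(tri, lower_dhp, lower_dhp.T)
    m_rec = np.where(tri.T, upper_rec, upper_rec.T)
    np.fill_diagonal(m_dhp, 0.0)
    np.fill_diagonal(m_rec, 0.0)
    return SlippageMatrix(list(labels), m_dhp, m_rec)


def slippage_summary(m: SlippageMatrix) -> dict:
    """Max/mean of each regime over off-diagonal cells, plus the contrast
    statistic mean(DHp regime) − mean(REC regime)."""
    n = len(m.labels)
    iu = np.triu_indices(n, k=1)
    dhp = m.m_dhp[iu]
    rec = m.m_rec[iu]
    return {
        "n_complexes": n,
        "n_pairs": len(dhp),
        "max_dhp": float(dhp.max()),
        "mean_dhp": float(dhp.mean()),
        "max_rec": float(rec.max()),
        "mean_rec": float(rec.mean()),
        "contrast": float(dhp.mean() - rec.mean()),
        "n_regime_violations": len(m.regime_violations),
    }
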