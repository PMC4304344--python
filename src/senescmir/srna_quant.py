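"""Known-miRNA quantification and the senescence differential screen.

Quantification is by perfect sequence identity against a miRBase-style
catalog: a library sequence contributes to a miRNA iff it equals the mature
sequence exactly, and identical family members all report the same abundance
(library totals are computed over sequences, so families never double-count).

The screen is the replicate-free design of a single library per stage: a
miRNA passing a 50 TP2M abundance floor in at least one library of the tissue
is flagged up (down) if its early- or late-senescence abundance is at least
``fold`` times (at most 1/``fold`` of) its mature-stage abundance, with a
pseudocount guarding zero denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .seqtools import rna_to_dna

SENESCENCE_STAGES = ("early_senescence", "late_senescence")


@dataclass
class MirnaCatalog:
    """Known mature miRNAs: unique ids, possibly shared sequences (families)."""

    entries: list[tuple[str, str]]  # (mirna id, DNA sequence)
    by_sequence: dict[str, list[str]] = field(init=False)

    def __post_init__(self):
        ids = [i for i, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate miRNA ids in catalog")
        self.entries = [(i, rna_to_dna(s)) for i, s in self.entries]
        self.by_sequence = {}
        for mid, seq in self.entries:
            self.by_sequence.setdefault(seq, []).append(mid)

    @classmethod
    def from_mapping(cls, mapping: dict[str, str]) -> "MirnaCatalog":
        return cls(list(mapping.items()))

    @classmethod
    def from_fasta(cls, path) -> "MirnaCatalog":
        from . import io

        return cls.from_mapping(io.read_fasta(path))

    def ids(self) -> list[str]:
        return [i for i, _ in self.entries]


def quantify_mirnas(abundance: pd.Series, catalog: MirnaCatalog) -> pd.Series:
    """Per-miRNA normalized abundance by perfect match (0 if absent)."""
    out = pd.Series(0.0, index=pd.Index(catalog.ids(), name="mirna"), name=abundance.name)
    for mid, seq in catalog.entries:
        if seq in abundance.index:
            out[mid] = float(abundance[seq])
    return out


def mirna_matrix(abundance_matrix: pd.DataFrame, catalog: MirnaCatalog) -> pd.DataFrame:
    """miRNA x library matrix from a sequence x library abundance matrix."""
    cols = [quantify_mirnas(abundance_matrix[c], catalog) for c in abundance_matrix.columns]
    return pd.concat(cols, axis=1)


def screen_differential(
    matrix: pd.DataFrame,
    tissue: str,
    floor: float = 50.0,
    fold: float = 3.0,
    pseudocount: float = 1.0,
    reference_stage: str = "mature",
) -> pd.DataFrame:
    """Flag senescence-regulated miRNAs in one tissue.

    ``matrix`` columns are ``{tissue}_{stage}`` library ids.  Fold change per
    senescence stage is (a_stage + c) / (a_reference + c).  Returns a frame
    with per-stage abundances, fold changes, ``passed_floor`` and
    ``candidate_up`` / ``candidate_down`` flags (flags require the floor).
    """
    ref_col = f"{tissue}_{reference_stage}"
    if ref_col not in matrix.columns:
        raise KeyError(f"missing reference library column {ref_col}")
    tissue_cols = [c for c in matrix.columns if c.startswith(f"{tissue}_")]
    sen_cols = [f"{tissue}_{s}" for s in SENESCENCE_STAGES if f"{tissue}_{s}" in matrix.columns]
    out = matrix[tissue_cols].copy()
    out["passed_floor"] = (matrix[tissue_cols] >= floor).any(axis=1)
    fc = {}
    for col in sen_cols:
        stage = col[len(tissue) + 1:]
        fc[stage] = (matrix[col] + pseudocount) / (matrix[ref_col] + pseudocount)
        out[f"fc_{stage}"] = fc[stage]
    fc_df = pd.DataFrame(fc)
    out["candidate_up"] = out["passed_floor"] & (fc_df >= fold).any(axis=1)
    out["candidate_down"] = out["passed_floor"] & (fc_df <= 1.0 / fold).any(axis=1)
    return out


def average_replicates(matrix: pd.DataFrame, groups: dict[str, list[str]]) -> pd.DataFrame:
    """Collapse replicate library columns by mean, enabling a replicate-aware
    screen (not the default: the canonical design has one library per stage).

    ``groups`` maps an output column name to the replicate columns to average.
    """
    out = {}
    for name, cols in groups.items():
        missing = [c for c in cols if c not in matrix.columns]
        if missing:
            raise KeyError(f"missing replicate columns {missing}")
        out[name] = matrix[cols].mean(axis=1)
    return pd.DataFrame(out)


def correlate_libraries(
    matrix: pd.DataFrame,
    lib_a: str,
    lib_b: str,
    floor: float = 50.0,
    log: bool = True,
) -> float:
    """R-squared of the least-squares fit between two libraries' miRNA
    abundances, over miRNAs passing the floor in either library.

    Computed on log10(TP2M + 1) by default (abundances span orders of
    magnitude); set ``log=False`` for the linear scale.
    """
    for col in (lib_a, lib_b):
        if col not in matrix.columns:
            raise KeyError(f"missing library column {col}")
    sub = matrix[[lib_a, lib_b]]
    sub = sub[(sub >= floor).any(axis=1)]
    if len(sub) < 3:
        raise ValueError("fewer than 3 miRNAs pass the floor in either library")
    x, y = sub[lib_a].to_numpy(), sub[lib_b].to_numpy()
    if log:
        x, y = np.log10(x + 1.0), np.log10(y + 1.0)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("degenerate (constant) abundance column")
    res = sp_stats.linregress(x, y)
    return float(res.rvalue**2)
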