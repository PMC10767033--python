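"""Candidate selection filters and novelty metrics for designed CDR sets.

The designed sequence is the concatenation of the three
complementarity-determining regions of the VHH scaffold (PDB 3DWT):
CDR1 (13 aa), CDR2 (10 aa) and CDR3 (16 aa), 39 residues total.  A
candidate passes selection iff it

1. has length 39,
2. contains no homopolymer run of 5 or more identical residues,
3. has ensemble-mean activity strictly above 0.6,
4. has a filter-solubility score strictly above 0.0, and
5. differs from the wild-type in each CDR segment by at least 3 residues.

Novelty is reported as the Hamming distance to the closest training
sequence.  The published five galectin-3 designs and the 3DWT wild-type
CDRs are shipped as reference inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .ensemble import PredictorEnsemble
from .objectives import SolubilityScorer

# Wild-type CDR segments of the 3DWT VHH scaffold.
WT_CDR1 = "GGSEYSYSTFSLG"
WT_CDR2 = "AIASMGGLTY"
WT_CDR3 = "VRGYFMRLPSSHNFRY"
WT_CDRS = WT_CDR1 + WT_CDR2 + WT_CDR3

# The five published galectin-3 designs (concatenated CDRs) and their
# reported Hamming distances to the closest training sequence.
TABLE1_VARIANTS: dict[str, str] = {
    "VHH1832": "SNQNNSNYNSYDYYFYNNSSYSYDSFNYYDDNNFDDYRR",
    "VHH1834": "ANGDNYNASYSDNYNYCDYSYSYDDYFNYYYNNNDDDRF",
    "VHH1835": "DNQNLNSYNDNNSFSYNSYYGSYDDYYYSYYNNFDNDRA",
    "VHH1836": "NNNDNSNNYSYYDSFYGDFNFYYNNQPNDDHYDVYDHNS",
    "VHH1837": "NQANFNSHRSYSSNNGSYYDDSFVNPPNDDHYDVYDHNS",
}
TABLE1_DISTANCES: dict[str, int] = {
    "VHH1832": 23, "VHH1834": 23, "VHH1835": 22, "VHH1836": 16, "VHH1837": 18,
}


@dataclass
class SelectionCriteria:
    required_length: int = 39
    max_homopolymer: int = 5          # a run of this length or longer fails
    min_mean_score: float = 0.6       # strict
    min_solubility: float = 0.0       # strict
    min_cdr_distance: int = 3
    cdr_boundaries: tuple[int, int, int] = (13, 23, 39)  # cumulative offsets
    wild_type: str = WT_CDRS
    homopolymer_mode: str = "run"     # "run" or "kmer" (tandem repeat)

    def __post_init__(self) -> None:
        if self.cdr_boundaries[-1] != self.required_length:
            raise ValueError("CDR boundaries must partition the required length")
        if len(self.wild_type) != self.required_length:
            raise ValueError("wild-type length must equal required_length")

    def segments(self, sequence: str) -> list[str]:
        b1, b2, b3 = self.cdr_boundaries
        return [sequence[:b1], sequence[b1:b2], sequence[b2:b3]]


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def min_distance_to_set(seq: str, training_set: list[str]) -> int:
    """Minimum Hamming distance from *seq* to any sequence in the set."""
    if not training_set:
        raise ValueError("training set is empty")
    return min(hamming(seq, t) for t in training_set)


def has_repeat(sequence: str, min_run: int = 5, mode: str = "run") -> bool:
    """Detect repetitive residues.

    ``run`` (default): a homopolymer of *min_run* identical consecutive
    residues.  ``kmer``: any adjacent tandem repeat covering at least
    *min_run* residues (e.g. ``ABABA`` for min_run=5).
    """
    n = len(sequence)
    if mode == "run":
        run = 1
        for i in range(1, n):
            run = run + 1 if sequence[i] == sequence[i - 1] else 1
            if run >= min_run:
                return True
        return False
    if mode == "kmer":
        for period in range(1, min_run // 2 + 1):
            streak = 0
            for i in range(period, n):
                streak = streak + 1 if sequence[i] == sequence[i - period] else 0
                if streak + period >= min_run:
                    return True
        return False
    raise ValueError(f"unknown homopolymer mode {mode!r}")


def apply_filters(
    candidates: pd.DataFrame,
    criteria: SelectionCriteria | None = None,
    ensemble: PredictorEnsemble | None = None,
    scorer: SolubilityScorer | None = None,
) -> pd.DataFrame:
    """Apply the five selection rules; returns per-rule flags plus ``passed``.

    *candidates* needs a ``sequence`` column.  Mean activity is taken
    from an ``f_mean`` column or recomputed with *ensemble*; the filter
    solubility comes from a ``sol_filter`` column or *scorer* (the
    filter-scorer slot is distinct from the objective's solubility
    scorer).  A wrong-length candidate fails rule 1 (and the CDR rule is
    evaluated as failed) rather than raising.
    """
    crit = criteria or SelectionCriteria()
    out = candidates.copy().reset_index(drop=True)
    seqs = out["sequence"].tolist()

    out["pass_length"] = [len(s) == crit.required_length for s in seqs]
    out["pass_repeat"] = [
        not has_repeat(s, crit.max_homopolymer, crit.homopolymer_mode) for s in seqs
    ]

    if "f_mean" in out.columns:
        means = out["f_mean"].astype(float)
    elif ensemble is not None:
        from .ensemble import ensemble_predict
        means = pd.Series([ensemble_predict(ensemble, s)[0] for s in seqs])
    else:
        raise ValueError("need an f_mean column or an ensemble to score candidates")
    out["f_mean"] = means
    out["pass_score"] = means > crit.min_mean_score

    if "sol_filter" in out.columns:
        sols = out["sol_filter"].astype(float)
    elif scorer is not None:
        sols = pd.Series([scorer(s) for s in seqs])
    else:
        raise ValueError("need a sol_filter column or a scorer for the solubility rule")
    out["sol_filter"] = sols
    out["pass_solubility"] = sols > crit.min_solubility

    wt_segs = crit.segments(crit.wild_type)
    cdr_ok = []
    for s in seqs:
        if len(s) != crit.required_length:
            cdr_ok.append(False)
            continue
        segs = crit.segments(s)
        cdr_ok.append(all(
            hamming(seg, wt) >= crit.min_cdr_distance
            for seg, wt in zip(segs, wt_segs)
        ))
    out["pass_cdr_distance"] = cdr_ok

    out["passed"] = (
        out["pass_length"] & out["pass_repeat"] & out["pass_score"]
        & out["pass_solubility"] & out["pass_cdr_distance"]
    )
    return out


def novelty_report(selected: list[str], training_set: list[str]) -> pd.DataFrame:
    """Per-sequence minimum Hamming distance to the training set."""
    return pd.DataFrame({
        "sequence": selected,
        "min_distance": [min_distance_to_set(s, training_set) for s in selected],
    })
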