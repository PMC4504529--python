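"""Subjective-analysis bookkeeping: the vessel-segment quality-score ledger.

Image quality is scored per vessel segment on a 5-point ordinal scale
(1 = no diagnostic vessel definition ... 5 = excellent) for every patient at
every dose level.  Segments that are occluded or surgically absent are
excluded identically at every dose level, so dose groups stay comparable.
Scores dichotomize into nondiagnostic (1-2) vs diagnostic (3-5).

Human reading is out of scope; ``synth_scores`` fills a ledger from a simple
monotone SNR -> quality model with reader noise, standing in for readers in
end-to-end runs.  It is a fixture generator, not a model of observer
performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LedgerError",
    "ScoreLedger",
    "build_ledger",
    "dichotomize",
    "synth_scores",
    "DIAGNOSTIC_THRESHOLD",
]

#: Scores at or above this value count as diagnostic.
DIAGNOSTIC_THRESHOLD = 3

SCORE_LABELS = {
    1: "no diagnostic vessel definition",
    2: "poor vessel definition",
    3: "moderate vessel definition",
    4: "good vessel definition",
    5: "excellent vessel definition",
}


class LedgerError(ValueError):
    """Inconsistent ledger construction (e.g. duplicate exclusions)."""


def dichotomize(score: int) -> str:
    """Map an ordinal 1-5 quality score to diagnostic / nondiagnostic."""
    score = int(score)
    if not 1 <= score <= 5:
        raise ValueError(f"quality score must be an integer in [1, 5], got {score}")
    return "diagnostic" if score >= DIAGNOSTIC_THRESHOLD else "nondiagnostic"


@dataclass
class ScoreLedger:
    """(segment x patient x dose level) table of quality scores.

    ``table`` has one row per cell with columns ``segment, patient,
    dose_level, score, excluded, reason``; ``score`` is NaN until assigned
    and always NaN for excluded cells.
    """

    table: pd.DataFrame
    dose_levels: tuple

    @property
    def n_total(self) -> int:
        return len(self.table)

    @property
    def n_excluded(self) -> int:
        return int(self.table["excluded"].sum())

    @property
    def n_scored(self) -> int:
        """Cells available for scoring (total minus excluded)."""
        return self.n_total - self.n_excluded

    def fill(self, scores: np.ndarray) -> None:
        """Assign scores to all non-excluded cells (in table row order)."""
        mask = ~self.table["excluded"]
        scores = np.asarray(scores)
        if scores.shape != (int(mask.sum()),):
            raise LedgerError("score vector does not match the scorable cell count")
        if not np.all((scores >= 1) & (scores <= 5) & (scores == scores.astype(int))):
            raise ValueError("scores must be integers in [1, 5]")
        self.table.loc[mask, "score"] = scores.astype(float)

    def dichotomized(self) -> pd.DataFrame:
        """Scored cells with an added diagnostic/nondiagnostic column."""
        scored = self.table[~self.table["excluded"] & self.table["score"].notna()].copy()
        scored["category"] = scored["score"].map(lambda s: dichotomize(int(s)))
        return scored

    def summary(self) -> dict:
        """Per-dose score distributions and diagnostic fractions."""
        out = {
            "n_total": self.n_total,
            "n_scored": self.n_scored,
            "n_excluded": self.n_excluded,
            "per_dose": {},
        }
        d = self.dichotomized()
        for level in self.dose_levels:
            sub = d[d["dose_level"] == level]
            counts = sub["score"].value_counts().to_dict()
            out["per_dose"][str(level)] = {
                "n": len(sub),
                "score_counts": {int(k): int(v) for k, v in sorted(counts.items())},
                "median_score": float(sub["score"].median()) if len(sub) else None,
                "diagnostic_fraction": float((sub["category"] == "diagnostic").mean())
                if len(sub)
                else None,
            }
        return out

    def to_csv(self, path) -> None:
        df = self.table.copy()
        df["score"] = df.apply(
            lambda r: "EXCLUDED" if r["excluded"] else (
                "" if pd.isna(r["score"]) else int(r["score"])
            ),
            axis=1,
        )
        df.to_csv(path, index=False)


def build_ledger(
    n_segments: int = 40,
    n_patients: int = 30,
    n_dose_levels: int = 4,
    exclusions: list[tuple[int, int]] | None = None,
    dose_levels: tuple | None = None,
) -> ScoreLedger:
    """Create an empty ledger over segments x patients x dose levels.

    ``exclusions`` lists (segment, patient) pairs; each pair is removed at
    *every* dose level, because an occluded or resected segment is absent
    from all reconstructions of the same acquisition.  Duplicate pairs or
    out-of-range indices raise :class:`LedgerError`.
    """
    if min(n_segments, n_patients, n_dose_levels) < 1:
        raise ValueError("all axis sizes must be positive")
    if dose_levels is None:
        dose_levels = tuple(range(n_dose_levels))
    elif len(dose_levels) != n_dose_levels:
        raise LedgerError("dose_levels labels do not match n_dose_levels")
    exclusions = list(exclusions or [])
    if len(set(exclusions)) != len(exclusions):
        raise LedgerError("duplicate exclusion entries")
    for seg, pat in exclusions:
        if not (0 <= seg < n_segments and 0 <= pat < n_patients):
            raise LedgerError(f"exclusion ({seg}, {pat}) out of range")
    excl = set(exclusions)

    seg, pat, lev = np.meshgrid(
        np.arange(n_segments), np.arange(n_patients), np.arange(n_dose_levels),
        indexing="ij",
    )
    table = pd.DataFrame(
        {
            "segment": seg.ravel(),
            "patient": pat.ravel(),
            "dose_level": [dose_levels[i] for i in lev.ravel()],
            "score": np.nan,
            "excluded": [
                (s, p) in excl for s, p in zip(seg.ravel(), pat.ravel())
            ],
            "reason": "",
        }
    )
    table.loc[table["excluded"], "reason"] = "occluded or resected"
    return ScoreLedger(table=table, dose_levels=tuple(dose_levels))


def synth_scores(
    ledger: ScoreLedger,
    snr_by_dose: dict,
    seed: int,
    slope: float = 2.0,
    intercept: float = -2.5,
    reader_sd: float = 0.5,
) -> ScoreLedger:
    """Fill a ledger from a monotone SNR -> score model with reader noise.

    Latent quality is ``slope * log(SNR) + intercept`` plus Gaussian reader
    noise of SD ``reader_sd``, rounded to the nearest score and clipped to
    [1, 5].  The defaults put a full-dose vessel SNR of ~33 near "excellent"
    and a quarter-dose SNR near "moderate".  Deterministic for a given seed;
    with ``reader_sd = 0`` the mapping is a pure function of SNR.
    """
    missing = [lv for lv in ledger.dose_levels if lv not in snr_by_dose]
    if missing:
        raise LedgerError(f"missing SNR for dose level(s) {missing}")
    for lv, snr in snr_by_dose.items():
        if not snr > 0:
            raise ValueError(f"SNR for dose level {lv} must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = ScoreLedger(table=ledger.table.copy(), dose_levels=ledger.dose_levels)
    mask = ~out.table["excluded"]
    snr = out.table.loc[mask, "dose_level"].map(snr_by_dose).to_numpy(dtype=float)
    latent = slope * np.log(snr) + intercept
    if reader_sd > 0:
        latent = latent + rng.normal(0.0, reader_sd, size=latent.shape)
    scores = np.clip(np.rint(latent), 1, 5).astype(int)
    out.fill(scores)
    return out
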