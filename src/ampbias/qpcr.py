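"""Relative expression and Degradation Proportion from qPCR CT values.

Amplicons tiled along a transcript are assayed in a pre-amplification
reference sample (PAM) and in amplified samples (e.g. one-cycle OCS,
two-cycle TCS).  With CT the cycle threshold, the relative expression of
amplicon ``i`` in sample ``j`` is

    R_ij = 2 ** -(CT(i, j) - CT(i, PAM))

which cancels per-amplicon efficiency differences against the reference.
The best-preserved amplicon attains ``max_i R_ij``; the Degradation
Proportion

    DP_ij = 1 - R_ij / max_i(R_ij)

lies in [0, 1]: 0 means no positional loss relative to the best-preserved
region, 1 means the region is completely gone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["QpcrPanel", "relative_expression", "degradation_proportion", "dp_table"]

REFERENCE_SAMPLE = "PAM"


class MissingReferenceError(ValueError):
    """An amplicon lacks a CT value in the reference sample."""


def relative_expression(ct_sample: float, ct_reference: float) -> float:
    """``R = 2 ** -(CT_sample - CT_reference)``; one extra cycle halves R."""
    if not (np.isfinite(ct_sample) and np.isfinite(ct_reference)):
        raise ValueError("CT values must be finite")
    return float(2.0 ** -(ct_sample - ct_reference))


@dataclass
class QpcrPanel:
    """CT measurements for the amplicons of one transcript.

    ``ct`` maps ``(amplicon_id, sample)`` to a CT value; technical replicate
    CTs are averaged on construction (:meth:`from_frame`).  ``amplicons``
    lists ``(amplicon_id, start position from the 5' end in bp)`` in assay
    order, which also breaks ties at the maximum R.
    """

    transcript_id: str
    amplicons: list[tuple[str, float]]
    ct: dict[tuple[str, str], float]
    reference: str = REFERENCE_SAMPLE
    _order: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self._order = [aid for aid, _ in self.amplicons]
        missing = [a for a in self._order if (a, self.reference) not in self.ct]
        if missing:
            raise MissingReferenceError(
                f"{self.transcript_id}: no reference ({self.reference}) CT for "
                f"amplicons {missing}"
            )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, transcript_id: str, reference: str = REFERENCE_SAMPLE
    ) -> "QpcrPanel":
        """Build a panel from long-format rows
        ``transcript_id, amplicon_id, start_5prime, sample, ct``."""
        sub = df[df["transcript_id"] == transcript_id]
        if sub.empty:
            raise ValueError(f"no rows for transcript {transcript_id!r}")
        amps = (
            sub[["amplicon_id", "start_5prime"]]
            .drop_duplicates("amplicon_id")
            .sort_values("start_5prime")
        )
        mean_ct = sub.groupby(["amplicon_id", "sample"])["ct"].mean()
        return cls(
            transcript_id=transcript_id,
            amplicons=list(amps.itertuples(index=False, name=None)),
            ct={k: float(v) for k, v in mean_ct.items()},
            reference=reference,
        )

    def samples(self) -> list[str]:
        return sorted({s for (_, s) in self.ct if s != self.reference})

    def relative_expressions(self, sample: str) -> pd.Series:
        """R per amplicon for one non-reference sample (assay order)."""
        r = {}
        for aid in self._order:
            if (aid, sample) in self.ct:
                r[aid] = relative_expression(self.ct[(aid, sample)], self.ct[(aid, self.reference)])
        if not r:
            raise ValueError(f"{self.transcript_id}: no CT values for sample {sample!r}")
        return pd.Series(r, name="r_rel")


def degradation_proportion(panel: QpcrPanel, sample: str) -> pd.DataFrame:
    """DP per amplicon for one sample: ``1 - R / max(R)``, clamped to [0, 1].

    All amplicons tied at the maximum R get DP exactly 0.  Returns a frame
    indexed by amplicon with columns ``r_rel`` and ``dp``.
    """
    r = panel.relative_expressions(sample)
    dp = np.clip(1.0 - r / r.max(), 0.0, 1.0)
    dp[r == r.max()] = 0.0
    return pd.DataFrame({"r_rel": r, "dp": dp})


def dp_table(df: pd.DataFrame, reference: str = REFERENCE_SAMPLE) -> pd.DataFrame:
    """DP for every transcript and non-reference sample in a long CT table.

    Output columns: ``transcript_id, amplicon_id, start_5prime, sample,
    r_rel, dp``.
    """
    out = []
    for tid in df["transcript_id"].unique():
        panel = QpcrPanel.from_frame(df, tid, reference=reference)
        starts = dict(panel.amplicons)
        for sample in panel.samples():
            res = degradation_proportion(panel, sample)
            res = res.reset_index(names="amplicon_id")
            res.insert(0, "transcript_id", tid)
            res.insert(2, "start_5prime", res["amplicon_id"].map(starts))
            res.insert(3, "sample", sample)
            out.append(res)
    return pd.concat(out, ignore_index=True)
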