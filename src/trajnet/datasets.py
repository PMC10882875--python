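"""Published CHARLS reference tables shipped with the package.

Small transcriptions of published summary values (top-10 linear-trajectory
table, baseline multimorbidity category percentages) used as fixed inputs
for arithmetic cross-checks; they are not derived from microdata.
"""

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd

from .network import LinearTrajectory


def _open(name: str):
    return resources.files("trajnet.data").joinpath(name).open()


def load_top10_trajectories() -> list[LinearTrajectory]:
    """The published top-10 linear trajectories as package structures."""
    with _open("reference_top10_trajectories.csv") as fh:
        df = pd.read_csv(fh)
    return [
        LinearTrajectory(
            d1=r.d1, d2=r.d2, d3=r.d3,
            median_onset_age_d1=float(r.median_onset_age_d1),
            n_12=int(r.n_12), median_t12=float(r.median_t12),
            n_123=int(r.n_123), median_t23=float(r.median_t23),
        )
        for r in df.itertuples(index=False)
    ]


def load_multimorbidity_reference() -> dict[str, float]:
    """Published weighted multimorbidity category percentages (0/1/2/3/4+)."""
    with _open("reference_multimorbidity.csv") as fh:
        df = pd.read_csv(fh, dtype={"category": str})
    return dict(zip(df["category"], df["percent"].astype(float)))


def mean_stage_durations(
    rows: list[LinearTrajectory], decimals: int = 1
) -> tuple[float, float]:
    """Arithmetic means of the per-trajectory median d1->d2 and d2->d3 gaps,
    rounded half-up to ``decimals`` (exact decimal arithmetic, so 5.05
    rounds to 5.1 rather than to the nearest binary float)."""
    q = Decimal(1).scaleb(-decimals)

    def mean_of(values) -> float:
        total = sum(Decimal(str(v)) for v in values)
        return float((total / len(values)).quantize(q, rounding=ROUND_HALF_UP))

    return (
        mean_of([r.median_t12 for r in rows]),
        mean_of([r.median_t23 for r in rows]),
    )
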