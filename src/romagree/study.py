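"""Study-level orchestration: measurement tables -> reliability report.

The central objects follow the model/results pattern:

* :class:`ReliabilityStudy` wraps a validated long-format measurement
  table (one row per case x movement x device x repetition);
* :meth:`ReliabilityStudy.fit` runs, per movement, the intra-device
  analysis for each device (repetition 1 vs repetition 2, single-measure
  ICC) and the inter-device analysis (per-case device means, average-
  measure ICC), returning a :class:`ReliabilityResults` that carries the
  report tables, the Bland-Altman scatter data, a ``summary()`` view and
  exporters.

Thin functional wrappers (:func:`read_measurements`,
:func:`run_intra_device`, :func:`run_inter_device`,
:func:`export_report`) expose the same steps individually.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as ag
from .catalog import ALL_MOVEMENTS, spec_for

REQUIRED_COLUMNS = (
    "participant_id",
    "side",
    "joint",
    "movement_id",
    "device",
    "repetition",
    "angle",
)

KEY_COLUMNS = ("participant_id", "side", "movement_id", "device", "repetition")

DEVICES = ("POM", "UG")

#: Fixed column order of an agreement report row.
REPORT_COLUMNS = (
    "movement_id",
    "n",
    "mean1",
    "sd1",
    "mean2",
    "sd2",
    "t",
    "p_value",
    "agreement_pct",
    "icc",
    "icc_ci_low",
    "icc_ci_high",
    "sem",
    "mdc95",
    "loa_low",
    "loa_high",
    "ccc",
    "grade",
)


class SchemaError(ValueError):
    """A measurement table violates the long-format schema."""


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Validate (and lightly normalise) a long-format measurement table."""
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    df = df.copy()
    df["repetition"] = pd.to_numeric(df["repetition"], errors="coerce")
    df["angle"] = pd.to_numeric(df["angle"], errors="coerce")
    df["side"] = df["side"].fillna("none").astype(str)

    bad = ~df["repetition"].isin([1, 2])
    if bad.any():
        i = int(df.index[bad][0])
        raise SchemaError(f"row {i}, column 'repetition': must be 1 or 2")
    df["repetition"] = df["repetition"].astype(int)

    bad = ~np.isfinite(df["angle"])
    if bad.any():
        i = int(df.index[bad][0])
        raise SchemaError(f"row {i}, column 'angle': not a finite number")

    bad = ~df["device"].isin(DEVICES)
    if bad.any():
        i = int(df.index[bad][0])
        raise SchemaError(
            f"row {i}, column 'device': must be one of {DEVICES}"
        )

    bad = ~df["side"].isin(["left", "right", "none"])
    if bad.any():
        i = int(df.index[bad][0])
        raise SchemaError(f"row {i}, column 'side': must be left/right/none")

    spine = df["movement_id"].astype(str).str.startswith("spine")
    bad = spine & (df["side"] != "none")
    if bad.any():
        i = int(df.index[bad][0])
        raise SchemaError(f"row {i}, column 'side': spine movements take side 'none'")

    dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        i = int(df.index[dup][0])
        raise SchemaError(
            f"row {i}: duplicate key {tuple(df.loc[i, list(KEY_COLUMNS)])}"
        )
    return df


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read and validate a measurement CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return validate_measurements(pd.read_csv(path))


def _apply_caps(df: pd.DataFrame) -> pd.DataFrame:
    """Saturate angles at each movement's catalog cap (idempotent)."""
    df = df.copy()
    for movement_id in df["movement_id"].unique():
        if movement_id not in ALL_MOVEMENTS:
            continue
        sides = df.loc[df["movement_id"] == movement_id, "side"].unique()
        spec = spec_for(movement_id, sides[0] if sides[0] != "none" else "none")
        if spec.cap_degrees is not None:
            m = df["movement_id"] == movement_id
            df.loc[m, "angle"] = df.loc[m, "angle"].clip(upper=spec.cap_degrees)
    return df


def _agreement_row(movement_id: str, a: np.ndarray, b: np.ndarray, form: str) -> dict:
    """One report row comparing paired columns ``a`` and ``b``."""
    sa, sb = ag.summarize(a), ag.summarize(b)
    tt = ag.t_test_from_summary(sa, sb)
    ba = ag.bland_altman(a, b)
    matrix = np.column_stack([a, b])
    try:
        icc_res = ag.icc(matrix, form=form)
        icc_fields = dict(
            icc=icc_res.estimate,
            icc_ci_low=icc_res.ci_low,
            icc_ci_high=icc_res.ci_high,
            grade=icc_res.grade,
        )
    except ag.DegenerateDataError:
        icc_fields = dict(icc=np.nan, icc_ci_low=np.nan, icc_ci_high=np.nan, grade="n/a")
    try:
        ccc = ag.lin_ccc(a, b)
    except ag.DegenerateDataError:
        ccc = np.nan
    return dict(
        movement_id=movement_id,
        n=sa.n,
        mean1=sa.mean,
        sd1=sa.sd,
        mean2=sb.mean,
        sd2=sb.sd,
        t=tt.t,
        p_value=tt.p,
        agreement_pct=ba.agreement_pct,
        sem=ba.sem,
        mdc95=ba.mdc95,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        ccc=ccc,
        **icc_fields,
    )


def _case_pivot(df: pd.DataFrame, movement_id: str, device: str) -> pd.DataFrame:
    """Complete-case repetition table for one movement and device."""
    sub = df[(df["movement_id"] == movement_id) & (df["device"] == device)]
    pivot = sub.pivot_table(
        index=["participant_id", "side"],
        columns="repetition",
        values="angle",
        aggfunc="first",
    )
    return pivot.reindex(columns=[1, 2]).dropna()


@dataclass
class ReliabilityResults:
    """Fitted reliability/agreement report.

    ``tables`` maps analysis name ("intra_POM", "intra_UG", "inter") to a
    report DataFrame in the fixed column order; ``ba_pairs`` maps
    (analysis, movement_id) to the Bland-Altman (mean, difference) pairs
    used for plotting.
    """

    tables: dict[str, pd.DataFrame]
    ba_pairs: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)

    def table(self, analysis: str) -> pd.DataFrame:
        return self.tables[analysis]

    def bland_altman_pairs(self, analysis: str, movement_id: str) -> pd.DataFrame:
        return self.ba_pairs[(analysis, movement_id)]

    # ---- reporting -----------------------------------------------------

    def summary(self) -> str:
        """Human-readable report, angles/ICC/p to 3 decimals."""
        lines = []
        titles = {
            "intra_POM": "Intra-device reliability, optical device (rep 1 vs rep 2, ICC(2,1))",
            "intra_UG": "Intra-device reliability, goniometer (rep 1 vs rep 2, ICC(2,1))",
            "inter": "Inter-device agreement (device means, ICC(2,2))",
        }
        for name, df in self.tables.items():
            lines.append(titles.get(name, name))
            lines.append("=" * len(lines[-1]))
            show = df.copy()
            for c in show.columns:
                if show[c].dtype.kind == "f":
                    show[c] = show[c].map(lambda v: f"{v:.3f}")
            lines.append(show.to_string(index=False))
            lines.append("")
        return "\n".join(lines)

    def audit(self, atol: float = 1e-9) -> None:
        """Column-relation consistency audit of every report row.

        Checks, for each row: LOA midpoint equals the bias (mean1 -
        mean2); MDC95/SEM equals 1.96*sqrt(2) exactly; the agreement
        percentage is an integer multiple of 100/n.  Raises
        ``AssertionError`` on the first violation.
        """
        for name, df in self.tables.items():
            for _, row in df.iterrows():
                mid = (row["loa_low"] + row["loa_high"]) / 2.0
                bias = row["mean1"] - row["mean2"]
                assert abs(mid - bias) <= max(atol, 1e-9 * max(1.0, abs(bias))), (
                    f"{name}/{row['movement_id']}: LOA midpoint {mid} != bias {bias}"
                )
                if row["sem"] > 0:
                    ratio = row["mdc95"] / row["sem"]
                    assert abs(ratio - ag.MDC_FACTOR) <= atol, (
                        f"{name}/{row['movement_id']}: MDC95/SEM {ratio}"
                    )
                else:
                    assert row["mdc95"] == 0.0
                count = row["agreement_pct"] * row["n"] / 100.0
                assert abs(count - round(count)) <= 1e-6, (
                    f"{name}/{row['movement_id']}: agreement {row['agreement_pct']}"
                    f" is not a multiple of 100/{row['n']}"
                )

    # ---- export --------------------------------------------------------

    def to_csv(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = []
        for name, df in self.tables.items():
            p = directory / f"report_{name}.csv"
            export_report(df, p, fmt="csv")
            out.append(p)
        for (analysis, movement_id), pairs in self.ba_pairs.items():
            p = directory / f"ba_{analysis}_{movement_id}.csv"
            pairs.to_csv(p, index=False)
            out.append(p)
        return out

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            name: df.to_dict(orient="records") for name, df in self.tables.items()
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return path

    def plot_bland_altman(self, analysis: str, movement_id: str, ax=None):
        """Bland-Altman scatter with bias and LOA lines (needs matplotlib)."""
        import matplotlib.pyplot as plt

        pairs = self.bland_altman_pairs(analysis, movement_id)
        row = self.tables[analysis].set_index("movement_id").loc[movement_id]
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(pairs["mean"], pairs["difference"], s=12)
        ax.axhline(row["mean1"] - row["mean2"], color="k")
        ax.axhline(row["loa_low"], color="k", linestyle="--")
        ax.axhline(row["loa_high"], color="k", linestyle="--")
        ax.set_xlabel("mean of paired measurements (deg)")
        ax.set_ylabel("difference (deg)")
        ax.set_title(f"{movement_id} ({analysis})")
        return ax


class ReliabilityStudy:
    """Reliability/agreement model over a long-format measurement table.

    Parameters
    ----------
    data
        Long-format measurements (validated on construction): columns
        participant_id, side, joint, movement_id, device, repetition,
        angle.
    cap_at_ingest
        Saturate angles at each movement's catalog normal-range cap
        before analysis (idempotent if the acquisition already capped).
    """

    def __init__(self, data: pd.DataFrame, cap_at_ingest: bool = False):
        data = validate_measurements(data)
        if cap_at_ingest:
            data = _apply_caps(data)
        self.data = data
        self.movements = [
            m for m in ALL_MOVEMENTS if m in set(data["movement_id"])
        ] or sorted(set(data["movement_id"]))

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "ReliabilityStudy":
        return cls(read_measurements(path), **kwargs)

    def case_counts(self) -> pd.Series:
        """Complete cases (all 2 devices x 2 repetitions) per movement."""
        counts = {}
        for m in self.movements:
            piv = self._inter_pivot(m)
            counts[m] = len(piv)
        return pd.Series(counts, name="n_complete")

    # ---- fitting -------------------------------------------------------

    def _inter_pivot(self, movement_id: str) -> pd.DataFrame:
        """Per-case device means (complete cases across both devices)."""
        sub = self.data[self.data["movement_id"] == movement_id]
        counts = sub.pivot_table(
            index=["participant_id", "side"],
            columns="device",
            values="angle",
            aggfunc="count",
        ).reindex(columns=list(DEVICES))
        means = sub.pivot_table(
            index=["participant_id", "side"],
            columns="device",
            values="angle",
            aggfunc="mean",
        ).reindex(columns=list(DEVICES))
        complete = (counts == 2).all(axis=1)
        return means[complete]

    def fit_intra(self, device: str) -> tuple[pd.DataFrame, dict]:
        if device not in DEVICES:
            raise ValueError(f"device must be one of {DEVICES}")
        rows = []
        pairs = {}
        for m in self.movements:
            piv = _case_pivot(self.data, m, device)
            if len(piv) < 2:
                warnings.warn(
                    f"movement {m!r}: fewer than 2 complete cases for {device}; skipped"
                )
                continue
            a, b = piv[1].to_numpy(), piv[2].to_numpy()
            rows.append(_agreement_row(m, a, b, form="single"))
            pairs[(f"intra_{device}", m)] = pd.DataFrame(
                {"mean": (a + b) / 2.0, "difference": a - b}
            )
        return pd.DataFrame(rows, columns=list(REPORT_COLUMNS)), pairs

    def fit_inter(self) -> tuple[pd.DataFrame, dict]:
        rows = []
        pairs = {}
        for m in self.movements:
            piv = self._inter_pivot(m)
            if len(piv) < 2:
                warnings.warn(
                    f"movement {m!r}: fewer than 2 complete cases across devices; skipped"
                )
                continue
            a, b = piv["POM"].to_numpy(), piv["UG"].to_numpy()
            rows.append(_agreement_row(m, a, b, form="average"))
            pairs[("inter", m)] = pd.DataFrame(
                {"mean": (a + b) / 2.0, "difference": a - b}
            )
        return pd.DataFrame(rows, columns=list(REPORT_COLUMNS)), pairs

    def fit(self) -> ReliabilityResults:
        """Run the full battery: intra per device plus inter-device."""
        tables = {}
        ba: dict[tuple[str, str], pd.DataFrame] = {}
        for device in DEVICES:
            if (self.data["device"] == device).any():
                df, pairs = self.fit_intra(device)
                tables[f"intra_{device}"] = df
                ba.update(pairs)
        if set(self.data["device"]) >= set(DEVICES):
            df, pairs = self.fit_inter()
            tables["inter"] = df
            ba.update(pairs)
        return ReliabilityResults(tables=tables, ba_pairs=ba)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def run_intra_device(table: pd.DataFrame, device: str) -> pd.DataFrame:
    """Repetition 1 vs 2 agreement per movement for one device."""
    df, _ = ReliabilityStudy(table).fit_intra(device)
    return df


def run_inter_device(table: pd.DataFrame) -> pd.DataFrame:
    """Device-mean agreement per movement (average-measures ICC)."""
    df, _ = ReliabilityStudy(table).fit_inter()
    return df


def export_report(rows: pd.DataFrame, path: str | Path, fmt: str = "csv") -> Path:
    """Write a report table with the fixed column order."""
    if len(rows) == 0:
        raise ValueError("cannot export an empty report")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = rows.reindex(columns=list(REPORT_COLUMNS))
    if fmt == "csv":
        out.to_csv(path, index=False)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(out.to_dict(orient="records"), fh, indent=2)
    else:
        raise ValueError("fmt must be 'csv' or 'json'")
    return path


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a report written by :func:`export_report`."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh), columns=list(REPORT_COLUMNS))
    return pd.read_csv(path)


def audit_report(rows: pd.DataFrame, atol: float = 1e-9) -> None:
    """Column-relation audit on a standalone report table."""
    ReliabilityResults(tables={"report": rows}).audit(atol=atol)
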