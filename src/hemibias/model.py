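"""Model/results interface for the interhemispheric-bias analysis.

:class:`HomotopicBiasModel` wraps a bilateral ROI time-course dataset and a
network layout; :meth:`~HomotopicBiasModel.fit` runs the full comparison —
within-subject and between-subject connectivity tables, per-region paired
t-tests of interhemispheric (homotopic) vs. intrahemispheric coupling with
Holm-corrected p-values and d_avg effect sizes, and the within-vs-between
contrast that asks whether the homotopic bias is subject-specific — and
returns a :class:`HomotopicBiasResults` with a ``summary()`` table.

Example
-------
>>> from hemibias import HomotopicBiasModel
>>> model = HomotopicBiasModel.from_preset("face", n_subjects=20,
...                                        run_lengths=[1500, 1500], seed=7)
>>> res = model.fit()
>>> print(res.summary())                     # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as hbstats
from .connectivity import (
    NetworkLayout,
    between_subject_table,
    region_summary,
    within_subject_table,
)
from .synthetic import ROITimecourseDataset, generate_dataset, preset_spec

COMPARISONS = (
    ("vs_intra_avg", "intra_avg_Zr"),
    ("vs_intra_high", "intra_high_Zr"),
)

_TEST_COLUMNS = ["region", "comparison", "mode", "n", "mean_diff", "t", "df",
                 "p", "p_adj", "d_avg", "direction"]


class HomotopicBiasModel:
    """Interhemispheric vs. intrahemispheric connectivity-bias analysis.

    Parameters
    ----------
    dataset
        :class:`~hemibias.synthetic.ROITimecourseDataset` (simulated or
        loaded from per-subject time-course files).
    layout
        Network layout; defaults to the dataset's regions under the
        dataset's network name.
    modes
        Which analyses to run: subset of ``("within", "between")``.
    selection
        How the highest intrahemispheric pairing is chosen: ``"group"``
        (highest group-mean Zr, one pairing per dataset — default) or
        ``"subject"`` (each subject's own maximum).
    average_space
        Between-subject per-subject aggregation: ``"z"`` (Fisher-transform
        then mean, default) or ``"r"``.
    contrast_method
        ``"paired"`` (default; same subjects in both analyses) or
        ``"welch"`` for the within-vs-between comparison.
    clip
        Clip |r| = 1 to a finite Zr instead of raising.
    """

    def __init__(
        self,
        dataset: ROITimecourseDataset,
        layout: NetworkLayout | None = None,
        modes: tuple[str, ...] = ("within", "between"),
        selection: str = "group",
        average_space: str = "z",
        contrast_method: str = "paired",
        clip: bool = True,
    ) -> None:
        self.dataset = dataset
        self.layout = layout or NetworkLayout(
            name=dataset.network, regions=dataset.regions
        )
        modes = tuple(modes)
        if not modes or any(m not in ("within", "between") for m in modes):
            raise ValueError("modes must be a non-empty subset of ('within', 'between')")
        self.modes = modes
        self.selection = selection
        self.average_space = average_space
        self.contrast_method = contrast_method
        self.clip = clip

    @classmethod
    def from_preset(
        cls,
        network: str,
        n_subjects: int,
        run_lengths,
        seed: int,
        **model_kwargs,
    ) -> "HomotopicBiasModel":
        """Simulate a named network regime and wrap it in a model."""
        spec = preset_spec(network)
        dataset = generate_dataset(spec, n_subjects, run_lengths, seed,
                                   network=network)
        return cls(dataset, **model_kwargs)

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "HomotopicBiasResults":
        tables: dict[str, pd.DataFrame] = {}
        summaries: dict[str, pd.DataFrame] = {}
        if "within" in self.modes:
            tables["within"] = within_subject_table(
                self.dataset, self.layout, clip=self.clip
            )
        if "between" in self.modes:
            tables["between"] = between_subject_table(
                self.dataset, self.layout, clip=self.clip,
                average_space=self.average_space,
            )
        for mode, table in tables.items():
            summaries[mode] = pd.concat(
                [region_summary(table, region, selection=self.selection)
                 for region in self.layout.regions],
                ignore_index=True,
            )

        fam = hbstats.family_size(self.layout)
        bias_tests = pd.concat(
            [self._mode_tests(summaries[mode], mode, fam) for mode in tables],
            ignore_index=True,
        ) if tables else pd.DataFrame(columns=_TEST_COLUMNS)

        contrast_tests = None
        if "within" in tables and "between" in tables:
            contrast_tests = self._contrast_tests(summaries, fam)

        return HomotopicBiasResults(
            model=self,
            tables=tables,
            summaries=summaries,
            bias_tests=bias_tests,
            contrast_tests=contrast_tests,
        )

    def _mode_tests(self, summary: pd.DataFrame, mode: str, fam: int) -> pd.DataFrame:
        """Per-region paired tests of homotopic vs. intra coupling."""
        rows = []
        for region in self.layout.regions:
            sub = summary[summary["region"] == region].sort_values("subject")
            inter = sub["inter_corresponding_Zr"].to_numpy()
            for comparison, col in COMPARISONS:
                other = sub[col].to_numpy()
                ok = ~(np.isnan(inter) | np.isnan(other))
                if ok.sum() < 3 or np.isnan(other).all():
                    rows.append((region, comparison, mode, int(ok.sum()),
                                 np.nan, np.nan, np.nan, np.nan, np.nan, 0))
                    continue
                t, df, p, d_avg = hbstats.paired_t_davg(inter[ok], other[ok])
                diff = float(np.mean(inter[ok] - other[ok]))
                rows.append((region, comparison, mode, int(ok.sum()), diff,
                             t, df, p, d_avg, int(np.sign(diff))))
        out = pd.DataFrame(
            rows,
            columns=["region", "comparison", "mode", "n", "mean_diff", "t",
                     "df", "p", "d_avg", "direction"],
        )
        out["p_adj"] = self._holm_by_family(out["p"].to_numpy(), fam)
        return out[_TEST_COLUMNS]

    def _contrast_tests(self, summaries: dict, fam: int) -> pd.DataFrame:
        """Within-vs-between contrast on inter - intra_high differences."""
        rows = []
        for region in self.layout.regions:
            diffs = {}
            for mode in ("within", "between"):
                sub = summaries[mode]
                sub = sub[sub["region"] == region].sort_values("subject")
                diffs[mode] = (
                    sub["inter_corresponding_Zr"] - sub["intra_high_Zr"]
                ).to_numpy()
            res = hbstats.within_between_contrast(
                diffs["within"], diffs["between"], method=self.contrast_method
            )
            rows.append((region, "within_vs_between", res["method"],
                         len(diffs["within"]),
                         float(np.mean(diffs["within"]) - np.mean(diffs["between"])),
                         res["t"], res["df"], res["p"], res["d_avg"],
                         int(np.sign(res["t"]))))
        out = pd.DataFrame(
            rows,
            columns=["region", "comparison", "method", "n", "mean_diff", "t",
                     "df", "p", "d_avg", "direction"],
        )
        out["p_adj"] = self._holm_by_family(out["p"].to_numpy(), fam)
        return out

    @staticmethod
    def _holm_by_family(pvals: np.ndarray, fam: int) -> np.ndarray:
        """Holm-adjust the non-NaN p-values against the family size."""
        adj = np.full_like(pvals, np.nan, dtype=float)
        ok = ~np.isnan(pvals)
        if ok.any():
            m = max(fam, int(ok.sum()))
            adj[ok] = hbstats.holm_adjust(pvals[ok], family_size=m)
        return adj


@dataclass
class HomotopicBiasResults:
    """Fitted results: connectivity tables, per-region tests, contrasts."""

    model: HomotopicBiasModel
    tables: dict[str, pd.DataFrame]
    summaries: dict[str, pd.DataFrame]
    bias_tests: pd.DataFrame
    contrast_tests: pd.DataFrame | None = None

    @property
    def within_table(self) -> pd.DataFrame | None:
        return self.tables.get("within")

    @property
    def between_table(self) -> pd.DataFrame | None:
        return self.tables.get("between")

    def class_means(self, mode: str = "within") -> pd.Series:
        """Group-mean Zr per pairing class for one mode."""
        table = self.tables[mode]
        return table.groupby("pair_class")["Zr"].mean()

    def summary(self, float_format: str = "%.3f") -> str:
        """Human-readable report in the style of a model results table."""
        layout = self.model.layout
        ds = self.model.dataset
        lines = [
            "Homotopic connectivity bias analysis",
            "=" * 68,
            f"Network: {layout.name}   regions: {', '.join(layout.regions)}",
            f"Subjects: {ds.n_subjects}   TRs: {ds.n_timepoints} "
            f"(runs: {list(ds.run_lengths)})",
            f"Holm family size: {hbstats.family_size(layout)} "
            f"({layout.n_regions} regions x 2 comparison types)",
            f"Highest-pair selection: {self.model.selection};  "
            f"between-subject averaging: {self.model.average_space}-space",
            "",
        ]
        show = self.bias_tests.copy()
        if not show.empty:
            show["d_avg"] = show["d_avg"].round(2)
            for mode in self.tables:
                lines.append(f"{mode.capitalize()}-subject paired tests "
                             "(interhemispheric - intrahemispheric):")
                block = show[show["mode"] == mode].drop(columns=["mode"])
                lines.append(block.to_string(index=False,
                                             float_format=float_format))
                lines.append("")
        if self.contrast_tests is not None:
            lines.append("Within-vs-between contrast "
                         "(inter - intra_high differences):")
            block = self.contrast_tests.copy()
            block["d_avg"] = block["d_avg"].round(2)
            lines.append(block.to_string(index=False, float_format=float_format))
            lines.append("")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        """JSON-serialisable bundle of the fitted results."""
        def records(df):
            return None if df is None else df.replace({np.nan: None}).to_dict("records")

        return {
            "network": self.model.layout.name,
            "regions": list(self.model.layout.regions),
            "n_subjects": self.model.dataset.n_subjects,
            "n_timepoints": self.model.dataset.n_timepoints,
            "run_lengths": list(self.model.dataset.run_lengths),
            "options": {
                "modes": list(self.model.modes),
                "selection": self.model.selection,
                "average_space": self.model.average_space,
                "contrast_method": self.model.contrast_method,
            },
            "class_means": {
                mode: {k: float(v) for k, v in self.class_means(mode).items()}
                for mode in self.tables
            },
            "bias_tests": records(self.bias_tests),
            "contrast_tests": records(self.contrast_tests),
        }

    def plot(self, mode: str = "within", ax=None):
        """Violin plot of subject-level Zr by pairing class (one mode)."""
        from .plotting import plot_pair_classes

        return plot_pair_classes(self.tables[mode], ax=ax,
                                 title=f"{self.model.layout.name} ({mode})")
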