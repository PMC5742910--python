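"""Model / Results interface tying images, entropy, and group statistics.

Two model classes in the statsmodels style:

* :class:`GroupComparisonModel` — fitted to a subject-level DataFrame
  (subject_id, group, age, gender, ben), its :meth:`~GroupComparisonModel.fit`
  returns a :class:`GroupComparisonResults` carrying every statistic of the
  two-group battery and a printed summary table.
* :class:`BrainEntropyModel` — fitted to raw component images plus subject
  metadata; :meth:`~BrainEntropyModel.fit` runs segmentation -> artifact
  removal -> entropy -> subject aggregation, then delegates the group
  comparison, returning a :class:`BrainEntropyResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as bstats
from .colors import DEFAULT_PALETTE, ColorPalette
from .entropy import NoRetainedPixelsError, SubjectBEN, image_ben
from .segmentation import ComponentImage
from .stats import Coding, ContingencyTable2x2, DEFAULT_CODING


@dataclass(frozen=True)
class SubjectRecord:
    """One row of the analysis: a subject's group, demographics, and BEN."""

    subject_id: str
    group: str  # "ADHD" or "control"
    age: float
    gender: str  # "male" or "female"
    ben: float

    def __post_init__(self) -> None:
        if self.group not in ("ADHD", "control"):
            raise ValueError(f"group must be 'ADHD' or 'control', got {self.group!r}")
        if self.gender not in ("male", "female"):
            raise ValueError(f"gender must be 'male' or 'female', got {self.gender!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

class GroupComparisonModel:
    """Two-group comparison of subject-level BEN, age, and gender.

    Parameters
    ----------
    data
        DataFrame with columns ``group`` ('ADHD'/'control'), ``age``,
        ``gender`` ('male'/'female'), and a value column (default ``ben``).
    coding
        Numeric codes for the binary variables; controls correlation signs.
    value_col
        Column holding the continuous outcome compared between groups.
    """

    def __init__(self, data: pd.DataFrame, coding: Coding = DEFAULT_CODING,
                 value_col: str = "ben"):
        required = {"group", "age", "gender", value_col}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data is missing columns: {sorted(missing)}")
        for grp in ("ADHD", "control"):
            if (data["group"] == grp).sum() < 2:
                raise ValueError(f"empty group: need >= 2 subjects in {grp!r}")
        self.data = data.reset_index(drop=True)
        self.coding = coding
        self.value_col = value_col

    @classmethod
    def from_records(cls, records: list[SubjectRecord],
                     coding: Coding = DEFAULT_CODING) -> "GroupComparisonModel":
        df = pd.DataFrame([r.__dict__ for r in records])
        return cls(df, coding=coding)

    def fit(self, equal_var: bool = True) -> "GroupComparisonResults":
        df = self.data
        col = self.value_col
        adhd = df.loc[df["group"] == "ADHD"]
        ctrl = df.loc[df["group"] == "control"]

        def _ms(s: pd.Series) -> tuple[float, float, int]:
            return float(s.mean()), float(s.std(ddof=1)), int(s.size)

        ben_t = bstats.t_test_two_sample(adhd[col], ctrl[col], equal_var=equal_var)
        ben_mw = bstats.mann_whitney_u(adhd[col], ctrl[col])
        age_mw = bstats.mann_whitney_u(adhd["age"], ctrl["age"])
        table = ContingencyTable2x2.from_labels(df["group"], df["gender"],
                                                self.coding)
        chi2 = bstats.chi_square_2x2(table)
        phi = bstats.phi_coefficient(table, self.coding)
        pbr = bstats.point_biserial(df[col], df["group"], self.coding)

        return GroupComparisonResults(
            model=self,
            n_adhd=len(adhd), n_control=len(ctrl),
            ben_adhd=_ms(adhd[col])[:2], ben_control=_ms(ctrl[col])[:2],
            age_adhd=_ms(adhd["age"])[:2], age_control=_ms(ctrl["age"])[:2],
            t_statistic=ben_t.t, t_p=ben_t.p, t_df=ben_t.df,
            ben_mw_u=ben_mw.u, ben_mw_z=ben_mw.z, ben_mw_p=ben_mw.p,
            age_mw_u=age_mw.u, age_mw_z=age_mw.z, age_mw_p=age_mw.p,
            gender_table=table, chi_square=chi2.chi2, chi_square_p=chi2.p,
            phi=phi.r, phi_p=phi.p,
            ben_group_r=pbr.r, ben_group_p=pbr.p,
        )


@dataclass
class GroupComparisonResults:
    """Fitted two-group battery; ``summary()`` prints the comparison table."""

    model: GroupComparisonModel = field(repr=False)
    n_adhd: int = 0
    n_control: int = 0
    ben_adhd: tuple[float, float] = (np.nan, np.nan)       # (mean, sd)
    ben_control: tuple[float, float] = (np.nan, np.nan)
    age_adhd: tuple[float, float] = (np.nan, np.nan)
    age_control: tuple[float, float] = (np.nan, np.nan)
    t_statistic: float = np.nan
    t_p: float = np.nan
    t_df: float = np.nan
    ben_mw_u: float = np.nan
    ben_mw_z: float = np.nan
    ben_mw_p: float = np.nan
    age_mw_u: float = np.nan
    age_mw_z: float = np.nan
    age_mw_p: float = np.nan
    gender_table: ContingencyTable2x2 | None = None
    chi_square: float = np.nan
    chi_square_p: float = np.nan
    phi: float = np.nan
    phi_p: float = np.nan
    ben_group_r: float = np.nan
    ben_group_p: float = np.nan

    def to_dict(self) -> dict:
        t = self.gender_table
        return {
            "n_adhd": self.n_adhd, "n_control": self.n_control,
            "ben_mean_adhd": self.ben_adhd[0], "ben_sd_adhd": self.ben_adhd[1],
            "ben_mean_control": self.ben_control[0], "ben_sd_control": self.ben_control[1],
            "age_mean_adhd": self.age_adhd[0], "age_sd_adhd": self.age_adhd[1],
            "age_mean_control": self.age_control[0], "age_sd_control": self.age_control[1],
            "t_statistic": self.t_statistic, "t_p": self.t_p, "t_df": self.t_df,
            "ben_mw_u": self.ben_mw_u, "ben_mw_z": self.ben_mw_z, "ben_mw_p": self.ben_mw_p,
            "age_mw_u": self.age_mw_u, "age_mw_z": self.age_mw_z, "age_mw_p": self.age_mw_p,
            "gender_counts": [[t.a, t.b], [t.c, t.d]] if t else None,
            "chi_square": self.chi_square, "chi_square_p": self.chi_square_p,
            "phi": self.phi, "phi_p": self.phi_p,
            "ben_group_r": self.ben_group_r, "ben_group_p": self.ben_group_p,
        }

    def to_frame(self) -> pd.DataFrame:
        """The comparison table as a DataFrame (one row per characteristic)."""
        t = self.gender_table
        rows = [
            {
                "characteristic": "age",
                "adhd": f"{self.age_adhd[0]:.2f} ± {self.age_adhd[1]:.2f}",
                "control": f"{self.age_control[0]:.2f} ± {self.age_control[1]:.2f}",
                "statistic": self.age_mw_z, "test": "Mann-Whitney Z",
                "p": self.age_mw_p,
            },
            {
                "characteristic": "gender (male/female)",
                "adhd": f"{t.a}/{t.b}", "control": f"{t.c}/{t.d}",
                "statistic": self.chi_square, "test": "Pearson chi2",
                "p": self.chi_square_p,
            },
            {
                "characteristic": "brain entropy (BEN)",
                "adhd": f"{self.ben_adhd[0]:.2f} ± {self.ben_adhd[1]:.2f}",
                "control": f"{self.ben_control[0]:.2f} ± {self.ben_control[1]:.2f}",
                "statistic": self.ben_mw_z, "test": "Mann-Whitney Z",
                "p": self.ben_mw_p,
            },
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text comparison table plus the t-test and correlations."""
        df = self.to_frame()
        lines = [
            "Group comparison (ADHD vs control)",
            "=" * 74,
            f"{'characteristic':<22}{'ADHD (n=%d)' % self.n_adhd:<16}"
            f"{'control (n=%d)' % self.n_control:<16}{'Z/chi2':>9}{'p':>9}",
            "-" * 74,
        ]
        for row in df.itertuples(index=False):
            lines.append(
                f"{row.characteristic:<22}{row.adhd:<16}{row.control:<16}"
                f"{row.statistic:>9.3f}{row.p:>9.3f}"
            )
        lines += [
            "-" * 74,
            f"t-test on BEN (pooled, df={self.t_df:.0f}): "
            f"t = {self.t_statistic:.3f}, p = {self.t_p:.3f}",
            f"BEN-group point-biserial: r = {self.ben_group_r:.3f}, "
            f"p = {self.ben_group_p:.3f}",
            f"gender-group phi: r = {self.phi:.3f}, p = {self.phi_p:.3f}",
            "=" * 74,
        ]
        return "\n".join(lines)

    def plot_group_bens(self, ax=None):
        """Bar chart of per-subject BEN, grouped and color-coded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        df = self.model.data.sort_values(["group", "subject_id"]
                                         if "subject_id" in self.model.data
                                         else ["group"])
        colors = df["group"].map({"ADHD": "tab:red", "control": "tab:blue"})
        ax.bar(range(len(df)), df[self.model.value_col], color=colors)
        ax.set_xlabel("subject")
        ax.set_ylabel("BEN (normalized)")
        ax.set_ylim(0, 1)
        handles = [plt.Rectangle((0, 0), 1, 1, color=c)
                   for c in ("tab:red", "tab:blue")]
        ax.legend(handles, ["ADHD", "control"], frameon=False)
        return ax


def build_table1(data: pd.DataFrame | list[SubjectRecord],
                 coding: Coding = DEFAULT_CODING) -> GroupComparisonResults:
    """Assemble the full comparison battery from subject records.

    Convenience wrapper: builds a :class:`GroupComparisonModel` and fits it.
    """
    if isinstance(data, pd.DataFrame):
        return GroupComparisonModel(data, coding=coding).fit()
    return GroupComparisonModel.from_records(data, coding=coding).fit()


# ---------------------------------------------------------------------------
# image-level model
# ---------------------------------------------------------------------------

class BrainEntropyModel:
    """Brain-entropy analysis of per-subject component images.

    Parameters
    ----------
    metadata
        DataFrame with subject_id, group, age, gender (one row per subject).
    images
        Mapping subject_id -> list of :class:`ComponentImage` (two per
        subject by default).
    palette
        Color profiles used for segmentation.
    normalize
        If True (default) group statistics run on the normalized BEN in
        [0, 1]; if False, on raw entropy bits in [0, 8].
    """

    def __init__(self, metadata: pd.DataFrame,
                 images: dict[str, list[ComponentImage]],
                 palette: ColorPalette = DEFAULT_PALETTE,
                 coding: Coding = DEFAULT_CODING,
                 images_per_subject: int = 2,
                 normalize: bool = True):
        required = {"subject_id", "group", "age", "gender"}
        missing = required - set(metadata.columns)
        if missing:
            raise ValueError(f"metadata is missing columns: {sorted(missing)}")
        if metadata.empty:
            raise ValueError("empty group: the subject table has no rows")
        absent = [s for s in metadata["subject_id"] if s not in images]
        if absent:
            raise ValueError(f"no images provided for subjects: {absent[:5]}")
        self.metadata = metadata.reset_index(drop=True)
        self.images = images
        self.palette = palette
        self.coding = coding
        self.images_per_subject = images_per_subject
        self.normalize = normalize

    @classmethod
    def from_cohort(cls, cohort, palette: ColorPalette = DEFAULT_PALETTE,
                    coding: Coding = DEFAULT_CODING,
                    normalize: bool = True) -> "BrainEntropyModel":
        """Build from a :class:`benmap.synthetic.Cohort`."""
        return cls(cohort.table, cohort.images, palette=palette, coding=coding,
                   images_per_subject=cohort.config.images_per_subject,
                   normalize=normalize)

    @classmethod
    def from_csv(cls, table_path: str | Path, image_root: str | Path | None = None,
                 palette: ColorPalette = DEFAULT_PALETTE,
                 coding: Coding = DEFAULT_CODING,
                 normalize: bool = True) -> "BrainEntropyModel":
        """Build from a subject CSV whose image_* columns point at rasters.

        Image paths are resolved relative to ``image_root`` (default: the
        CSV's directory).
        """
        table_path = Path(table_path)
        if not table_path.exists():
            raise FileNotFoundError(f"subject table not found: {table_path}")
        root = Path(image_root) if image_root is not None else table_path.parent
        meta = pd.read_csv(table_path)
        img_cols = sorted(c for c in meta.columns if c.startswith("image_"))
        if not img_cols:
            raise ValueError(f"{table_path} has no image_* columns")
        images: dict[str, list[ComponentImage]] = {}
        for rec in meta.itertuples(index=False):
            sid = str(rec.subject_id)
            imgs = []
            for k, col in enumerate(img_cols):
                p = root / str(getattr(rec, col))
                if not p.exists():
                    raise FileNotFoundError(f"image not found: {p}")
                imgs.append(ComponentImage.from_file(p, subject_id=sid,
                                                     component_index=k))
            images[sid] = imgs
        return cls(meta, images, palette=palette, coding=coding,
                   images_per_subject=len(img_cols), normalize=normalize)

    def fit(self, equal_var: bool = True) -> "BrainEntropyResults":
        per_image_rows = []
        subject_results: list[SubjectBEN] = []
        for sid in self.metadata["subject_id"]:
            imgs = self.images[sid]
            if len(imgs) != self.images_per_subject:
                raise ValueError(
                    f"subject {sid!r}: expected {self.images_per_subject} "
                    f"images, got {len(imgs)}"
                )
            rows = []
            sb = None
            for k, img in enumerate(imgs, start=1):
                try:
                    res = image_ben(img, self.palette)
                except NoRetainedPixelsError:
                    sb = SubjectBEN(
                        subject_id=sid, image_bens=(), image_bits=(),
                        ben=float("nan"), entropy_bits=float("nan"),
                        excluded=True,
                        reason=f"image {k}: no retained pixels after segmentation",
                    )
                    break
                rows.append({
                    "subject_id": sid, "image": k, "n_pixels": res.n_pixels,
                    "entropy_bits": res.entropy_bits, "ben": res.ben,
                })
            if sb is None:
                bens = tuple(r["ben"] for r in rows)
                bits = tuple(r["entropy_bits"] for r in rows)
                sb = SubjectBEN(
                    subject_id=sid, image_bens=bens, image_bits=bits,
                    ben=float(np.mean(bens)), entropy_bits=float(np.mean(bits)),
                )
                per_image_rows.extend(rows)
            subject_results.append(sb)

        per_image = pd.DataFrame(
            per_image_rows,
            columns=["subject_id", "image", "n_pixels", "entropy_bits", "ben"],
        )
        bens = {sb.subject_id: sb for sb in subject_results}
        per_subject = self.metadata.copy()
        per_subject["ben"] = [bens[s].ben for s in per_subject["subject_id"]]
        per_subject["entropy_bits"] = [
            bens[s].entropy_bits for s in per_subject["subject_id"]
        ]
        per_subject["excluded"] = [
            bens[s].excluded for s in per_subject["subject_id"]
        ]
        excluded = [
            (sb.subject_id, sb.reason) for sb in subject_results if sb.excluded
        ]

        analysed = per_subject.loc[~per_subject["excluded"]]
        value_col = "ben" if self.normalize else "entropy_bits"
        gc_model = GroupComparisonModel(analysed, coding=self.coding,
                                        value_col=value_col)
        comparison = gc_model.fit(equal_var=equal_var)
        return BrainEntropyResults(
            model=self, per_image=per_image, per_subject=per_subject,
            excluded=excluded, group_comparison=comparison,
        )


@dataclass
class BrainEntropyResults:
    """Per-image and per-subject entropies plus the fitted group battery."""

    model: BrainEntropyModel = field(repr=False)
    per_image: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_subject: pd.DataFrame = field(default_factory=pd.DataFrame)
    excluded: list[tuple[str, str]] = field(default_factory=list)
    group_comparison: GroupComparisonResults | None = None

    def summary(self) -> str:
        lines = [
            f"Brain-entropy analysis: {len(self.per_subject)} subjects, "
            f"{len(self.per_image)} images analysed",
        ]
        if self.excluded:
            lines.append("Excluded subjects:")
            lines += [f"  {sid}: {reason}" for sid, reason in self.excluded]
        lines.append("")
        lines.append(self.group_comparison.summary())
        return "\n".join(lines)
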