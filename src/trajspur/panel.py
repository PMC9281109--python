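"""Long-format longitudinal panel container.

A panel holds repeated measures ``y`` of ``N`` subjects over up to ``t``
occasions in long format (one row per subject-occasion).  Simulated panels
additionally carry the generating subgroup label of each subject
(``true_group``), which downstream diagnostics use to compare estimated
trajectories with the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_REQUIRED = ("subject_id", "occasion", "time", "y")


@dataclass
class LongitudinalPanel:
    """Repeated measures in long format.

    Parameters
    ----------
    data
        DataFrame with columns ``subject_id`` (integer label), ``occasion``
        (integer 1..t), ``time`` (numeric time entering the polynomials),
        ``y`` (measurement) and optionally ``true_group`` (integer
        generating subgroup, constant within subject).
    """

    data: pd.DataFrame
    _balanced_cache: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"panel is missing required columns: {missing}")
        if self.data.duplicated(["subject_id", "occasion"]).any():
            raise ValueError("(subject_id, occasion) pairs must be unique")
        if self.data["y"].isna().any():
            raise ValueError("panel contains missing y values; drop them first")
        if self.has_true_group:
            per_subject = self.data.groupby("subject_id")["true_group"].nunique()
            if (per_subject > 1).any():
                raise ValueError("true_group must be constant within subject")
        counts = self.data.groupby("subject_id").size()
        if (counts < 1).any():
            raise ValueError("every subject needs at least one observation")
        self.data = self.data.sort_values(["subject_id", "occasion"]).reset_index(drop=True)

    # -- basic properties -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def n_occasions(self) -> int:
        return int(self.data["occasion"].max())

    @property
    def has_true_group(self) -> bool:
        return "true_group" in self.data.columns and self.data["true_group"].notna().all()

    @property
    def subject_ids(self) -> np.ndarray:
        return self.data["subject_id"].unique()

    def true_groups(self) -> np.ndarray:
        """Per-subject generating group labels (simulated panels only)."""
        if not self.has_true_group:
            raise ValueError("panel has no true_group column")
        return self.data.groupby("subject_id", sort=True)["true_group"].first().to_numpy()

    @property
    def is_balanced(self) -> bool:
        """True when every subject shares one common time grid."""
        return self.balanced() is not None

    # -- dense views ------------------------------------------------------
    def balanced(self) -> tuple[np.ndarray, np.ndarray] | None:
        """Return ``(Y, times)`` with ``Y`` of shape (N, t) if the panel is
        balanced (every subject observed on an identical time grid), else
        ``None``.  The dense view enables fully vectorised likelihoods."""
        if self._balanced_cache is not None:
            return self._balanced_cache[0]
        counts = self.data.groupby("subject_id").size()
        result = None
        if counts.nunique() == 1:
            t = int(counts.iloc[0])
            times = self.data["time"].to_numpy()[:t]
            all_times = self.data["time"].to_numpy().reshape(-1, t)
            if np.all(all_times == times):
                Y = self.data["y"].to_numpy().reshape(-1, t)
                result = (Y, times)
        self._balanced_cache = (result,)
        return result

    def by_subject(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """List of per-subject ``(times, y)`` arrays, ordered by subject_id."""
        out = []
        for _, grp in self.data.groupby("subject_id", sort=True):
            out.append((grp["time"].to_numpy(), grp["y"].to_numpy()))
        return out

    # -- I/O --------------------------------------------------------------
    def to_csv(self, path) -> None:
        cols = list(_REQUIRED) + (["true_group"] if "true_group" in self.data.columns else [])
        self.data[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LongitudinalPanel":
        """Read a long-format delimited file.

        Minimally requires ``subject_id``, ``time`` and ``y`` columns;
        ``occasion`` is derived from the rank of ``time`` within subject
        when absent.
        """
        df = pd.read_csv(path)
        if "occasion" not in df.columns:
            if not {"subject_id", "time", "y"} <= set(df.columns):
                raise ValueError("CSV needs columns subject_id, time, y")
            df["occasion"] = (
                df.groupby("subject_id")["time"].rank(method="first").astype(int)
            )
        return cls(df)
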