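"""Two-group nested experiment designs (subjects nested in groups, technical replicates in subjects)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExperimentDesign"]


@dataclass
class ExperimentDesign:
    """Group/subject structure for a two-group design with a random subject intercept.

    Samples belong to subjects, subjects are nested in groups.  The fixed-effect
    design matrix ``X`` is cell-means (one column per group), ``Z`` indicates
    subjects, and the default contrast ``L`` tests group1 − group2.

    Parameters
    ----------
    sample_ids : sample identifiers, one per column of the expression matrix.
    group : group label per sample (exactly two levels).
    subject : subject label per sample; every subject must map to one group.
    contrast : contrast over the group-mean coefficients (default [1, -1]).
    """

    sample_ids: list
    group: np.ndarray
    subject: np.ndarray
    contrast: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.group = np.asarray(self.group)
        self.subject = np.asarray(self.subject)
        n = len(self.sample_ids)
        if not (len(self.group) == len(self.subject) == n):
            raise ValueError("sample_ids, group and subject must have equal length")
        if n == 0:
            raise ValueError("design has no samples")
        # sorted group labels: the contrast direction depends on label order,
        # not on which sample happens to come first
        self.groups = np.sort(pd.unique(self.group))
        if len(self.groups) != 2:
            raise ValueError(f"exactly two groups required, got {len(self.groups)}")
        # nesting: each subject in exactly one group
        sub_to_grp = {}
        for s, g in zip(self.subject, self.group):
            if s in sub_to_grp and sub_to_grp[s] != g:
                raise ValueError(f"subject {s!r} appears in more than one group")
            sub_to_grp[s] = g
        self.subjects = pd.unique(self.subject)
        if self.contrast is None:
            self.contrast = np.array([1.0, -1.0])
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.contrast.shape != (2,):
            raise ValueError("contrast must have one entry per group")
        if not np.any(self.contrast != 0):
            raise ValueError("contrast must be nonzero")

    # -- basic structure -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def subjects_per_group(self) -> dict:
        out: dict = {}
        for g in self.groups:
            out[g] = len(pd.unique(self.subject[self.group == g]))
        return out

    @property
    def replicates_per_subject(self) -> dict:
        return {s: int(np.sum(self.subject == s)) for s in self.subjects}

    @property
    def balanced(self) -> bool:
        """True iff every group has the same number of subjects and every subject
        the same number of technical replicates."""
        spg = set(self.subjects_per_group.values())
        rps = set(self.replicates_per_subject.values())
        return len(spg) == 1 and len(rps) == 1

    @property
    def n_s(self) -> int:
        """Biological replicates (subjects) per group; balanced designs only."""
        spg = set(self.subjects_per_group.values())
        if len(spg) != 1:
            raise ValueError("n_s undefined for unbalanced designs")
        return spg.pop()

    @property
    def n_r(self) -> int:
        """Technical replicates per subject; balanced designs only."""
        rps = set(self.replicates_per_subject.values())
        if len(rps) != 1:
            raise ValueError("n_r undefined for unbalanced designs")
        return rps.pop()

    # -- matrices --------------------------------------------------------
    def fixed_effects_matrix(self) -> np.ndarray:
        """Cell-means fixed-effect design X (n_samples × 2)."""
        X = np.zeros((self.n_samples, 2))
        for j, g in enumerate(self.groups):
            X[self.group == g, j] = 1.0
        return X

    def random_effects_matrix(self) -> np.ndarray:
        """Subject indicator matrix Z (n_samples × n_subjects)."""
        Z = np.zeros((self.n_samples, self.n_subjects))
        for j, s in enumerate(self.subjects):
            Z[self.subject == s, j] = 1.0
        return Z

    def sorted_order(self) -> np.ndarray:
        """Stable sample order grouping columns by (group, subject)."""
        gidx = np.array([list(self.groups).index(g) for g in self.group])
        sidx = np.array([list(self.subjects).index(s) for s in self.subject])
        return np.lexsort((sidx, gidx))

    # -- construction ----------------------------------------------------
    @classmethod
    def from_frame(cls, samples: pd.DataFrame, contrast=None) -> "ExperimentDesign":
        """Build a design from a sample sheet with columns sample_id, group, subject."""
        required = {"sample_id", "group", "subject"}
        missing = required - set(samples.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        return cls(
            sample_ids=list(samples["sample_id"]),
            group=samples["group"].to_numpy(),
            subject=samples["subject"].to_numpy(),
            contrast=contrast,
        )

    @classmethod
    def balanced_two_group(cls, n_s: int, n_r: int) -> "ExperimentDesign":
        """Canonical balanced design: groups g1/g2, n_s subjects each, n_r replicates."""
        ids, grp, sub = [], [], []
        for g in (1, 2):
            for s in range(1, n_s + 1):
                for r in range(1, n_r + 1):
                    ids.append(f"g{g}_s{s}_r{r}")
                    grp.append(f"g{g}")
                    sub.append(f"g{g}_s{s}")
        return cls(sample_ids=ids, group=np.array(grp), subject=np.array(sub))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "group": self.group, "subject": self.subject}
        )
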