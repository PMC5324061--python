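"""Subject-by-variable categorical tables for matched case-control analyses.

A :class:`CohortTable` holds the analysis table of a matched (nested)
case-control study: one row per subject, one categorical column per
variable, a binary outcome, and a matched-set identifier linking each case
to its matched controls.  Every variable carries a *role* tag:

``outcome``
    the binary disease indicator (exactly one such variable),
``metabolite``
    an ordered quantile category derived from a plasma concentration,
``snp``
    a genotype category (common / heterozygous / homozygous variant, or the
    collapsed two-group coding),
``environment``
    any other covariate (smoking, BMI group, ...),
``matching``
    a variable used in the matched design (sex, age group, cohort, ...);
    matching variables are constant within a matched set and are never
    entered as covariates in conditional models.

Tables round-trip through tab-separated text with a YAML sidecar schema
recording roles and ordered category labels, so runs are reproducible from
plain-text artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

#: Sentinel category used for explicitly-missing environmental values.
MISSING = "missing"

ROLES = ("outcome", "metabolite", "snp", "environment", "matching")


@dataclass
class CohortTable:
    """Categorical analysis table with role tags and matched-set structure.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per subject.  Must contain ``subject_id`` and
        ``matched_set_id`` columns; every other column is a categorical
        variable.
    roles : dict
        Map from variable name to one of :data:`ROLES`.  Exactly one
        variable must have the ``outcome`` role.
    """

    data: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "subject_id" not in self.data.columns:
            raise ValueError("data must contain a 'subject_id' column")
        if "matched_set_id" not in self.data.columns:
            raise ValueError("data must contain a 'matched_set_id' column")
        if self.data["matched_set_id"].isna().any():
            raise ValueError("matched_set_id must be non-null for all subjects")
        unknown = set(self.roles) - set(self.data.columns)
        if unknown:
            raise ValueError(f"roles given for unknown variables: {sorted(unknown)}")
        bad = {v: r for v, r in self.roles.items() if r not in ROLES}
        if bad:
            raise ValueError(f"invalid roles: {bad}")
        outcomes = self.variables("outcome")
        if len(outcomes) != 1:
            raise ValueError(
                f"exactly one outcome variable required, found {outcomes}"
            )
        # normalize variable columns to pandas categoricals
        for v in self.roles:
            if not isinstance(self.data[v].dtype, pd.CategoricalDtype):
                self.data[v] = self.data[v].astype("category")

    # -- accessors ---------------------------------------------------------

    def variables(self, *roles: str) -> list[str]:
        """Variable names, optionally restricted to the given roles."""
        if not roles:
            return list(self.roles)
        return [v for v, r in self.roles.items() if r in roles]

    @property
    def outcome(self) -> str:
        return self.variables("outcome")[0]

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def case_mask(self) -> np.ndarray:
        """Boolean array, True for cases (outcome category '1' or 'case')."""
        col = self.data[self.outcome]
        s = col.astype(str)
        return (s == "1") | (s == "case") | (s == "True")

    def categories(self, variable: str) -> list[str]:
        return [str(c) for c in self.data[variable].cat.categories]

    # -- views -------------------------------------------------------------

    def complete_cases(self, variables: list[str] | None = None) -> "CohortTable":
        """Drop subjects with missing values in the given variables.

        The explicit :data:`MISSING` category does not count as missing; only
        genuine NA codes do (the complete-case policy applies to metabolite
        and SNP variables, while environmental variables carry an explicit
        missing category).
        """
        variables = variables if variables is not None else self.variables()
        keep = ~self.data[variables].isna().any(axis=1)
        return CohortTable(self.data.loc[keep].reset_index(drop=True).copy(),
                           dict(self.roles))

    def matched_sets(self) -> "pd.core.groupby.DataFrameGroupBy":
        return self.data.groupby("matched_set_id", observed=True, sort=True)

    def subset(self, mask: np.ndarray, drop_orphan_sets: bool = True) -> "CohortTable":
        """Row subset; optionally drop matched sets left without a case."""
        sub = self.data.loc[np.asarray(mask)].copy()
        if drop_orphan_sets:
            case = CohortTable(sub.reset_index(drop=True), dict(self.roles)).case_mask
            sub = sub.reset_index(drop=True)
            has_case = sub.loc[case, "matched_set_id"].unique()
            sub = sub[sub["matched_set_id"].isin(has_case)]
        return CohortTable(sub.reset_index(drop=True), dict(self.roles))

    def encoded(self, variables: list[str] | None = None
                ) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Integer-coded complete-case matrix for the learning algorithms.

        Returns
        -------
        codes : (n, p) int32 array of category codes
        cards : (p,) int array of category counts
        names : list of variable names, in column order
        """
        variables = variables if variables is not None else self.variables()
        tab = self.complete_cases(variables)
        codes = np.empty((tab.n_subjects, len(variables)), dtype=np.int32)
        cards = np.empty(len(variables), dtype=np.int64)
        for j, v in enumerate(variables):
            col = tab.data[v].cat
            codes[:, j] = col.codes
            cards[j] = len(col.categories)
        return codes, cards, list(variables)

    # -- text round-trip ----------------------------------------------------

    def to_tsv(self, path, schema_path=None) -> None:
        """Write the table as TSV with a YAML sidecar schema."""
        path = str(path)
        schema_path = schema_path or path + ".schema.yaml"
        self.data.to_csv(path, sep="\t", index=False)
        schema = {
            "roles": dict(self.roles),
            "categories": {v: self.categories(v) for v in self.roles},
        }
        with open(schema_path, "w") as fh:
            yaml.safe_dump(schema, fh, sort_keys=True)

    @classmethod
    def from_tsv(cls, path, schema_path=None) -> "CohortTable":
        path = str(path)
        schema_path = schema_path or path + ".schema.yaml"
        with open(schema_path) as fh:
            schema = yaml.safe_load(fh)
        df = pd.read_csv(path, sep="\t", dtype=str)
        for v, cats in schema["categories"].items():
            df[v] = pd.Categorical(df[v], categories=[str(c) for c in cats],
                                   ordered=True)
        return cls(df, schema["roles"])
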