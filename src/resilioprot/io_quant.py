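"""Reading and writing the tabular formats the pipeline touches.

The universal input is a :class:`ProteinQuantTable`: a proteins x samples
intensity matrix (label-free quantification scale, typically 1e6-1e8) with
peptide-evidence metadata and a sample -> phenotype-group annotation.

Input dialects
--------------
* minimal TSV: ``Protein IDs``, ``Gene names``, ``Peptides``,
  ``Unique peptides``, then one intensity column per sample;
* proteinGroups-style TSV: same, with intensity columns prefixed
  ``Intensity <sample>`` (the prefix is stripped to form sample ids).

A stored ``0`` or blank intensity cell is normalised to *missing* on read:
in label-free data a zero means "not quantified", not "absent at zero
abundance".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnnotationError, DuplicateKeyError, FormatError

REQUIRED_COLUMNS = ("Protein IDs", "Gene names", "Peptides", "Unique peptides")
INTENSITY_PREFIX = "Intensity "
VALID_GROUPS = ("resilient", "susceptible", "control")


@dataclass
class ProteinQuantTable:
    """Proteins x samples intensity matrix plus evidence metadata and labels.

    Attributes
    ----------
    proteins : pandas.DataFrame
        Indexed by protein accession; columns ``gene``, ``peptides``,
        ``unique_peptides``.
    intensities : pandas.DataFrame
        Same index; one column per sample, ``NaN`` encodes missing.
    sample_group : dict
        Maps every sample id to one of ``resilient | susceptible | control``.
    """

    proteins: pd.DataFrame
    intensities: pd.DataFrame
    sample_group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- views ---------------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.proteins.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.sample_group[s] == group]

    def labels_for(self, groups: tuple[str, str]) -> pd.Series:
        """Group label per sample, restricted to the two contrast groups."""
        keep = [s for s in self.sample_ids if self.sample_group[s] in groups]
        return pd.Series({s: self.sample_group[s] for s in keep}, name="group").loc[keep]

    def subset_samples(self, sample_ids: list[str]) -> "ProteinQuantTable":
        return ProteinQuantTable(
            proteins=self.proteins.copy(),
            intensities=self.intensities[sample_ids].copy(),
            sample_group={s: self.sample_group[s] for s in sample_ids},
        )

    def subset_proteins(self, protein_ids) -> "ProteinQuantTable":
        return ProteinQuantTable(
            proteins=self.proteins.loc[protein_ids].copy(),
            intensities=self.intensities.loc[protein_ids].copy(),
            sample_group=dict(self.sample_group),
        )

    # -- contract ------------------------------------------------------
    def validate(self) -> None:
        if self.proteins.index.has_duplicates:
            dupes = self.proteins.index[self.proteins.index.duplicated()].tolist()
            raise DuplicateKeyError(f"duplicate protein ids: {dupes[:5]}")
        if not self.proteins.index.equals(self.intensities.index):
            raise FormatError("protein metadata and intensity matrix are misaligned")
        missing_ann = [s for s in self.intensities.columns if s not in self.sample_group]
        if missing_ann:
            raise AnnotationError(f"samples without group annotation: {missing_ann}")
        bad_groups = {g for g in self.sample_group.values() if g not in VALID_GROUPS}
        if bad_groups:
            raise AnnotationError(f"unknown group labels: {sorted(bad_groups)}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise FormatError("negative intensity encountered")
        pep = self.proteins["peptides"].to_numpy()
        upe = self.proteins["unique_peptides"].to_numpy()
        if (pep < 0).any() or (upe < 0).any():
            raise FormatError("negative peptide counts")
        if (upe > pep).any():
            bad = self.proteins.index[upe > pep].tolist()
            raise FormatError(f"unique_peptides > peptides for: {bad[:5]}")


def read_annotation(path) -> dict[str, str]:
    """Read a ``sample,group`` annotation table (comma- or tab-separated)."""
    ann = pd.read_csv(path, sep=None, engine="python", dtype=str)
    cols = {c.strip().lower(): c for c in ann.columns}
    if "sample" not in cols or "group" not in cols:
        raise FormatError("annotation file must have 'sample' and 'group' columns")
    mapping = dict(zip(ann[cols["sample"]].str.strip(), ann[cols["group"]].str.strip()))
    return mapping


def read_quant_table(path, annotation_path) -> ProteinQuantTable:
    """Read a quantification TSV plus annotation into a validated table.

    Zeros and blanks in intensity cells become missing; row and column
    order are preserved exactly as stored.
    """
    df = pd.read_csv(path, sep="\t", dtype={"Protein IDs": str, "Gene names": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column: {col!r}")
    sample_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    if not sample_cols:
        raise FormatError("no intensity columns found")
    if all(c.startswith(INTENSITY_PREFIX) for c in sample_cols):
        rename = {c: c[len(INTENSITY_PREFIX):] for c in sample_cols}
    else:
        rename = {c: c for c in sample_cols}

    annotation = read_annotation(annotation_path)
    unannotated = [rename[c] for c in sample_cols if rename[c] not in annotation]
    if unannotated:
        raise AnnotationError(f"samples missing from annotation: {unannotated}")

    ids = df["Protein IDs"].astype(str)
    proteins = pd.DataFrame(
        {
            "gene": df["Gene names"].fillna("").astype(str).values,
            "peptides": df["Peptides"].astype(int).values,
            "unique_peptides": df["Unique peptides"].astype(int).values,
        },
        index=pd.Index(ids, name="protein_id"),
    )
    intens = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    intens = intens.rename(columns=rename)
    intens.index = proteins.index
    # LFQ convention: zero == not quantified
    intens = intens.mask(intens == 0.0)

    groups = {rename[c]: annotation[rename[c]] for c in sample_cols}
    return ProteinQuantTable(proteins=proteins, intensities=intens, sample_group=groups)


def write_quant_table(table: ProteinQuantTable, path, annotation_path=None) -> None:
    """Write a table back to the minimal TSV dialect (missing -> blank)."""
    out = pd.DataFrame(
        {
            "Protein IDs": table.proteins.index,
            "Gene names": table.proteins["gene"].values,
            "Peptides": table.proteins["peptides"].values,
            "Unique peptides": table.proteins["unique_peptides"].values,
        }
    )
    for s in table.sample_ids:
        out[s] = table.intensities[s].values
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
    if annotation_path is not None:
        ann = pd.DataFrame(
            {"sample": table.sample_ids,
             "group": [table.sample_group[s] for s in table.sample_ids]}
        )
        ann.to_csv(annotation_path, index=False)


# Columns rendered in scientific notation (significance measures).
_SCI_COLUMNS = frozenset({"p", "q", "p_value", "q_value"})


def write_results_table(records: pd.DataFrame, path, float_decimals: int = 3) -> None:
    """Write a stage result table as TSV with fixed float rendering.

    Scores and other floats get ``float_decimals`` decimals; p/q columns are
    rendered in scientific notation so small significance values survive.
    """
    out = records.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            if col in _SCI_COLUMNS:
                out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.3e}")
            else:
                out[col] = out[col].map(
                    lambda v: "" if pd.isna(v) else f"{v:.{float_decimals}f}"
                )
    out.to_csv(path, sep="\t", index=False)
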