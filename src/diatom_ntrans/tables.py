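"""Tabular containers and TSV I/O for the transporter-clade pipeline.

The atomic unit of observation is a *sample*: one station, one depth
stratum (surface ``SRF`` or deep-chlorophyll-maximum ``DCM``), one
plankton size fraction.  Samples are identified by the string key
``"<station>|<depth>|<fraction>"``.  Environmental variables are
measured at the station x depth level, so environmental tables are
keyed by ``"<station>|<depth>"`` (a *site*).

All tables are written as TSV with a header row, features as rows and
samples as columns (counts/occurrences) or sites as rows (environment).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

DEPTHS = ("SRF", "DCM")
SIZE_FRACTIONS = ("0.8-5", "5-20", "20-180", "180-2000")

LAYERS = ("raw_reads", "mrna_occurrence", "dna_occurrence")

#: the nine environmental predictors used for niche modeling
ENV_PREDICTORS = (
    "chlorophyll_a",      # mg/m^3, in situ
    "iron",               # nmol/l, model climatology
    "par",                # mol quanta m^-2 d^-1, satellite monthly mean
    "nh4",                # umol/l, annual surface mean
    "no2_no3",            # umol/l, in situ
    "no3",                # umol/l, in situ
    "temperature",        # degrees C, in situ
    "nitracline_depth",   # m
    "sampling_depth",     # categorical: 0 = SRF, 1 = DCM
)

#: predictors that are continuous (the correlation cap applies to these)
CONTINUOUS_PREDICTORS = ENV_PREDICTORS[:-1]


class SchemaError(ValueError):
    """A table violated its schema; the message names the offending field."""


def sample_key(station: str, depth: str, fraction: str) -> str:
    return f"{station}|{depth}|{fraction}"


def site_key(station: str, depth: str) -> str:
    return f"{station}|{depth}"


def split_sample_key(key: str) -> tuple[str, str, str]:
    station, depth, fraction = key.split("|")
    return station, depth, fraction


@dataclasses.dataclass
class CladeAbundanceTable:
    """Clade x sample matrix in one meta-omics layer.

    Parameters
    ----------
    values
        clade x sample matrix (rows indexed by clade name, columns by
        sample key).  Integer reads for the raw layer, nonnegative reals
        for occurrence layers.
    layer
        one of ``raw_reads``, ``mrna_occurrence``, ``dna_occurrence``.
    clade_meta
        per-clade frame with columns ``family`` (AMT1/NRT2), ``clade_id``
        (roman numeral within family) and ``kb_covered`` (kb of gene
        sequence covered with reads, the density denominator).
    sample_meta
        per-sample frame with columns ``station``, ``depth``,
        ``fraction`` and ``diatom_total`` (total diatom-mapped reads in
        that sample, the library-size denominator).
    """

    values: pd.DataFrame
    layer: str
    clade_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def validate(self) -> "CladeAbundanceTable":
        if self.layer not in LAYERS:
            raise SchemaError(f"unknown layer {self.layer!r}")
        v = self.values
        if not v.index.equals(self.clade_meta.index):
            raise SchemaError("values rows and clade_meta index differ")
        if not v.columns.equals(self.sample_meta.index):
            raise SchemaError("values columns and sample_meta index differ")
        for col in ("family", "clade_id", "kb_covered"):
            if col not in self.clade_meta.columns:
                raise SchemaError(f"clade_meta missing column {col!r}")
        for col in ("station", "depth", "fraction", "diatom_total"):
            if col not in self.sample_meta.columns:
                raise SchemaError(f"sample_meta missing column {col!r}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise SchemaError("values: non-numeric cells")
        if np.isnan(arr).any():
            raise SchemaError("values: missing cells not allowed")
        if (arr < 0).any():
            raise SchemaError("values: negative entries")
        if self.layer == "raw_reads" and not np.array_equal(arr, np.round(arr)):
            raise SchemaError("values: raw_reads layer must be integer-valued")
        bad_depth = set(self.sample_meta["depth"]) - set(DEPTHS)
        if bad_depth:
            raise SchemaError(f"sample_meta.depth: unknown strata {sorted(bad_depth)}")
        bad_frac = set(self.sample_meta["fraction"]) - set(SIZE_FRACTIONS)
        if bad_frac:
            raise SchemaError(f"sample_meta.fraction: unknown fractions {sorted(bad_frac)}")
        if (self.sample_meta["diatom_total"] <= 0).any():
            raise SchemaError("sample_meta.diatom_total: must be positive")
        dup = self.clade_meta.groupby("family")["clade_id"].apply(lambda s: s.duplicated().any())
        if dup.any():
            raise SchemaError("clade_meta.clade_id: duplicated within a family")
        return self

    @property
    def families(self) -> list[str]:
        return list(dict.fromkeys(self.clade_meta["family"]))

    def subset_family(self, family: str) -> "CladeAbundanceTable":
        mask = self.clade_meta["family"] == family
        return CladeAbundanceTable(
            values=self.values.loc[mask],
            layer=self.layer,
            clade_meta=self.clade_meta.loc[mask],
            sample_meta=self.sample_meta,
        )

    def subset_fraction(self, fraction: str) -> "CladeAbundanceTable":
        mask = self.sample_meta["fraction"] == fraction
        return CladeAbundanceTable(
            values=self.values.loc[:, mask],
            layer=self.layer,
            clade_meta=self.clade_meta,
            sample_meta=self.sample_meta.loc[mask],
        )

    def with_values(self, values: pd.DataFrame, layer: str) -> "CladeAbundanceTable":
        return CladeAbundanceTable(values, layer, self.clade_meta, self.sample_meta)


def validate_env(env: pd.DataFrame) -> pd.DataFrame:
    """Validate an environmental table (site x variable).

    One row per site key; the nine standard predictors must be present,
    extra columns (screen-only variables) are allowed.  Missing values
    are allowed (empty cells in TSV) and surface as NaN.
    """
    missing = [c for c in ENV_PREDICTORS if c not in env.columns]
    if missing:
        raise SchemaError(f"env missing predictors: {missing}")
    if env.index.duplicated().any():
        dups = env.index[env.index.duplicated()].tolist()
        raise SchemaError(f"env: duplicate site keys {dups[:3]}")
    for col in env.columns:
        if not np.issubdtype(env[col].dtype, np.number):
            raise SchemaError(f"env.{col}: non-numeric cells")
    bad = set(env["sampling_depth"].dropna().unique()) - {0, 1}
    if bad:
        raise SchemaError("env.sampling_depth: must be 0 (SRF) or 1 (DCM)")
    return env


# ---------------------------------------------------------------------------
# TSV round-trips


def write_matrix(df: pd.DataFrame, path: Path | str, index_label: str = "feature") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: Path | str, index_label: str = "feature") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = index_label
    return df


def write_counts(table: CladeAbundanceTable, out_dir: Path | str, prefix: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(table.values, out / f"{prefix}_counts.tsv", index_label="clade")
    table.clade_meta.to_csv(out / "clade_meta.tsv", sep="\t", index_label="clade")
    table.sample_meta.to_csv(out / f"{prefix}_sample_meta.tsv", sep="\t", index_label="sample")


def read_counts(out_dir: Path | str, prefix: str, layer: str) -> CladeAbundanceTable:
    out = Path(out_dir)
    values = read_matrix(out / f"{prefix}_counts.tsv", index_label="clade")
    clade_meta = pd.read_csv(out / "clade_meta.tsv", sep="\t", index_col=0)
    sample_meta = pd.read_csv(out / f"{prefix}_sample_meta.tsv", sep="\t", index_col=0)
    return CladeAbundanceTable(values, layer, clade_meta, sample_meta).validate()


def write_env(env: pd.DataFrame, path: Path | str) -> None:
    env.to_csv(path, sep="\t", index_label="site")


def read_env(path: Path | str) -> pd.DataFrame:
    return validate_env(pd.read_csv(path, sep="\t", index_col=0))
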