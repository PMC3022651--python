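"""Readers and writers for the tab-delimited tables the pipeline consumes.

The canonical matrix layout is TSV with sample ids in the first row and
probeset ids in the first column. Present/absent call matrices share the
layout with cells restricted to the MAS5 detection codes P (present),
M (marginal) and A (absent). Annotation tables are two columns
(probeset, gene symbol) with no header; symbols are uppercased at ingest
so case conventions (mouse ``Gstt1`` vs human ``GSTT1``) cannot split a
gene across datasets.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from coexpr_meta.errors import ValidationError

CALL_CODES = frozenset({"P", "M", "A"})


@dataclass(frozen=True)
class ExpressionDataset:
    """One study's probeset x sample intensity matrix with optional calls.

    Parameters
    ----------
    name
        Label of the dataset (used in meta-analysis output columns).
    probeset_ids, sample_ids
        Ordered, unique identifiers for rows and columns.
    intensities
        Non-negative normalized intensities, shape
        ``(len(probeset_ids), len(sample_ids))``.
    calls
        Optional detection-call matrix of the same shape, codes in
        ``{P, M, A}``.
    gene_of
        Partial probeset -> gene-symbol mapping (uppercased symbols).

    The number of sample columns, :attr:`n_samples`, is the weight this
    dataset carries in the meta-analysis.
    """

    name: str
    probeset_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    intensities: np.ndarray
    calls: np.ndarray | None = None
    gene_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "probeset_ids", tuple(self.probeset_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", inten)
        _check_unique(self.probeset_ids, "probeset id")
        _check_unique(self.sample_ids, "sample id")
        if inten.shape != (len(self.probeset_ids), len(self.sample_ids)):
            raise ValidationError(
                f"dataset {self.name!r}: intensity shape {inten.shape} does not "
                f"match {len(self.probeset_ids)} probesets x "
                f"{len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(inten)):
            raise ValidationError(f"dataset {self.name!r}: non-finite intensity")
        if np.any(inten < 0):
            raise ValidationError(f"dataset {self.name!r}: negative intensity")
        if self.calls is not None:
            calls = np.asarray(self.calls, dtype="U1")
            object.__setattr__(self, "calls", calls)
            if calls.shape != inten.shape:
                raise ValidationError(
                    f"dataset {self.name!r}: calls shape {calls.shape} does not "
                    f"match intensities {inten.shape}"
                )
            bad = set(np.unique(calls)) - CALL_CODES
            if bad:
                raise ValidationError(
                    f"dataset {self.name!r}: illegal call code(s) {sorted(bad)}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row_index(self, probeset_id: str) -> int:
        return self.probeset_ids.index(probeset_id)

    def mean_intensity(self) -> np.ndarray:
        """Per-probeset mean intensity across samples."""
        return self.intensities.mean(axis=1)

    def present_fraction(self) -> np.ndarray | None:
        """Per-probeset fraction of samples called P, or None without calls.

        Marginal (M) calls count as not present.
        """
        if self.calls is None:
            return None
        return (self.calls == "P").mean(axis=1)

    def with_annotation(self, mapping: dict[str, str]) -> "ExpressionDataset":
        """Return a copy with gene annotation attached (symbols uppercased)."""
        return replace(self, gene_of={p: s.upper() for p, s in mapping.items()})


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {kind}: {i!r}")
        seen.add(i)


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, header=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_expression_matrix(path, name: str) -> ExpressionDataset:
    """Read a TSV intensity matrix (first row samples, first column probesets).

    Raises
    ------
    ValidationError
        On duplicate probeset/sample ids, or a non-numeric or empty cell
        (named by its row/column coordinate).
    """
    df = _read_table(path)
    _check_unique(df.index, "probeset id")
    _check_unique(df.columns, "sample id")
    def _bad_cell(mask):
        i, j = np.argwhere(mask)[0]
        raise ValidationError(
            f"non-numeric or empty cell at probeset {df.index[i]!r}, "
            f"sample {df.columns[j]!r} (value {df.iat[i, j]!r})"
        )

    if df.isna().to_numpy().any():
        _bad_cell(df.isna().to_numpy())
    try:
        # numpy's parser is correctly rounded (round-trips repr output)
        values = df.to_numpy(dtype=float)
    except (ValueError, TypeError):
        coerced = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        _bad_cell(np.isnan(coerced))
    if not np.all(np.isfinite(values)):
        _bad_cell(~np.isfinite(values))
    return ExpressionDataset(
        name=name,
        probeset_ids=tuple(df.index),
        sample_ids=tuple(df.columns),
        intensities=values,
    )


def read_calls(path, dataset: ExpressionDataset) -> ExpressionDataset:
    """Attach a P/M/A call matrix to ``dataset``, aligning rows/columns by id.

    Row and column order in the file need not match the intensity matrix;
    the id sets must match exactly.
    """
    df = _read_table(path)
    _check_unique(df.index, "probeset id")
    _check_unique(df.columns, "sample id")
    for kind, have, want in (
        ("probeset", set(df.index), set(dataset.probeset_ids)),
        ("sample", set(df.columns), set(dataset.sample_ids)),
    ):
        if have != want:
            missing = sorted(want - have)
            extra = sorted(have - want)
            raise ValidationError(
                f"calls/{kind} id mismatch for dataset {dataset.name!r}: "
                f"missing {missing}, unexpected {extra}"
            )
    df = df.loc[list(dataset.probeset_ids), list(dataset.sample_ids)]
    values = df.to_numpy(dtype=str)
    bad = np.argwhere(~np.isin(values, sorted(CALL_CODES)))
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"illegal call code {values[i, j]!r} at probeset "
            f"{dataset.probeset_ids[i]!r}, sample {dataset.sample_ids[j]!r}"
        )
    return replace(dataset, calls=values)


def read_annotation(path) -> dict[str, str]:
    """Read a two-column (probeset, gene symbol) TSV into a mapping.

    Symbols are uppercased. A probeset listed twice with conflicting
    symbols is an error; repeated identical rows are tolerated. An empty
    file yields an empty mapping.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return {}
    if df.shape[1] != 2:
        raise ValidationError(
            f"annotation table must have 2 columns, found {df.shape[1]}"
        )
    mapping: dict[str, str] = {}
    for probeset, symbol in df.itertuples(index=False):
        symbol = str(symbol).upper()
        prior = mapping.get(probeset)
        if prior is not None and prior != symbol:
            raise ValidationError(
                f"probeset {probeset!r} annotated to conflicting symbols "
                f"{prior!r} and {symbol!r}"
            )
        mapping[str(probeset)] = symbol
    return mapping


def write_expression_matrix(dataset: ExpressionDataset, path) -> None:
    """Write the intensity matrix as TSV with full float round-trip precision."""
    with open(path, "w") as fh:
        fh.write("probeset\t" + "\t".join(dataset.sample_ids) + "\n")
        for pid, row in zip(dataset.probeset_ids, dataset.intensities):
            fh.write(pid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def write_calls_matrix(dataset: ExpressionDataset, path) -> None:
    if dataset.calls is None:
        raise ValidationError(f"dataset {dataset.name!r} has no calls to write")
    with open(path, "w") as fh:
        fh.write("probeset\t" + "\t".join(dataset.sample_ids) + "\n")
        for pid, row in zip(dataset.probeset_ids, dataset.calls):
            fh.write(pid + "\t" + "\t".join(row) + "\n")


def write_annotation(mapping: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for probeset, symbol in mapping.items():
            fh.write(f"{probeset}\t{symbol}\n")


def write_results_table(results, path, dataset_names=None) -> None:
    """Write meta-analysis rows as TSV, ordered by decreasing combined Z.

    Columns: gene, one correlation column per dataset (empty where the
    gene was absent from that dataset), meta_z (2 decimals), p_value and
    fdr (scientific, 3 significant digits).
    """
    results = list(results)
    if dataset_names is None:
        dataset_names = []
        for res in results:
            for ds in res.r_by_dataset:
                if ds not in dataset_names:
                    dataset_names.append(ds)
    ordered = sorted(results, key=lambda r: (-r.z_combined, r.gene))
    buf = io.StringIO()
    buf.write("\t".join(["gene", *dataset_names, "meta_z", "p_value", "fdr"]) + "\n")
    for res in ordered:
        cells = [res.gene]
        for ds in dataset_names:
            r = res.r_by_dataset.get(ds)
            cells.append("" if r is None else f"{r:.2f}")
        cells += [f"{res.z_combined:.2f}", f"{res.p_two:.2e}", f"{res.p_bonf:.2e}"]
        buf.write("\t".join(cells) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_results_table(path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t", dtype={"gene": str})
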