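"""Seeded generator of multi-dataset expression fixtures with a planted module.

The meta-analysis's only distributional assumption is a per-dataset
Pearson correlation between each gene and the target, so the generator
uses a latent-factor construction: per dataset a standard-normal target
factor ``f`` is drawn per sample; a planted gene's latent value is
``beta * f + sqrt(1 - beta^2) * noise`` (population correlation exactly
``beta``), a null gene's latent value is independent noise. Latent
values map to intensities by a per-gene affine transform around a
lognormal baseline, which preserves the correlation exactly.

Realism knobs mirrored from the filtering rules: a fraction of null
genes is forced below the intensity filter; present/absent calls are
drawn with probability rising logistically in intensity through
``call_midpoint``; each gene can drop out of individual datasets; genes
may carry several probesets with independent probe-level noise, the
lowest-noise probeset being the intended collapse winner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from coexpr_meta.errors import ValidationError
from coexpr_meta.expression_io import (
    ExpressionDataset,
    write_annotation,
    write_calls_matrix,
    write_expression_matrix,
)

_LOG_500 = math.log(500.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic fixture.

    Defaults emulate four white-adipose microarray studies of 40, 28,
    35 and 13 samples, 1000 genes with a 20-gene module planted at
    correlation 0.8 around the target.
    """

    n_datasets: int = 4
    samples_per_dataset: tuple[int, ...] = (40, 28, 35, 13)
    n_genes: int = 1000
    n_planted: int = 20
    beta: float = 0.8
    probesets_per_gene: int = 1
    baseline_log_mean: float = _LOG_500  # lognormal median ~= 500
    baseline_log_sd: float = 0.7
    low_expr_fraction: float = 0.05
    dropout_fraction: float = 0.1
    call_midpoint: float = 100.0
    seed: int = 0
    # secondary knobs
    target: str = "NNAT"
    intensity_cv: float = 0.15  # affine slope per latent sd, as fraction of baseline
    probe_noise_sd: float = 0.05  # latent-scale noise of the winner probeset
    extra_probe_noise_sd: float = 0.8  # noise of every additional probeset
    call_slope: float = 25.0  # intensity units per logistic unit

    def __post_init__(self) -> None:
        if self.n_datasets < 1 or len(self.samples_per_dataset) != self.n_datasets:
            raise ValidationError(
                "samples_per_dataset must list one size per dataset"
            )
        if any(n < 4 for n in self.samples_per_dataset):
            raise ValidationError("every dataset needs >= 4 samples")
        if not 0 < self.n_planted < self.n_genes:
            raise ValidationError("need 0 < n_planted < n_genes")
        if not 0 <= self.beta <= 1:
            raise ValidationError("beta must be in [0, 1]")
        if self.probesets_per_gene < 1:
            raise ValidationError("probesets_per_gene must be >= 1")
        for name in ("low_expr_fraction", "dropout_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.intensity_cv <= 0 or self.call_slope <= 0:
            raise ValidationError("intensity_cv and call_slope must be positive")


@dataclass(frozen=True)
class Truth:
    """Ground truth of a generated fixture."""

    target: str
    planted_genes: tuple[str, ...]
    beta_of: dict[str, float]
    collapse_winner: dict[str, str]  # gene -> intended winning probeset
    dropped: dict[str, tuple[str, ...]]  # dataset name -> genes absent
    low_expr_genes: tuple[str, ...]


def _gene_names(config: SyntheticConfig) -> list[str]:
    width = max(4, len(str(config.n_genes)))
    return [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]


def generate(config: SyntheticConfig | None = None):
    """Generate the datasets and their ground truth.

    Returns
    -------
    (datasets, truth)
        ``datasets`` is a list of :class:`ExpressionDataset` with calls
        and gene annotation attached; ``truth`` records planted genes,
        per-dataset dropouts and intended collapse winners. The same
        seed yields bit-identical output.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    target = config.target.upper()
    genes = _gene_names(config)
    planted = genes[: config.n_planted]
    nulls = genes[config.n_planted:]

    n_low = int(round(config.low_expr_fraction * config.n_genes))
    n_low = min(n_low, len(nulls))
    low_expr = tuple(sorted(rng.choice(nulls, size=n_low, replace=False))) if n_low else ()
    low_set = set(low_expr)

    # dropout mask: gene x dataset; the target never drops out and a
    # planted gene keeps at least one dataset
    drop = rng.random((config.n_genes, config.n_datasets)) < config.dropout_fraction
    for gi in range(config.n_planted):
        if drop[gi].all():
            drop[gi, rng.integers(config.n_datasets)] = False

    ppg = config.probesets_per_gene
    probe_sds = np.full(ppg, config.extra_probe_noise_sd)
    probe_sds[0] = config.probe_noise_sd
    winner = {g: f"{g}_ps1" for g in genes}

    datasets: list[ExpressionDataset] = []
    dropped: dict[str, tuple[str, ...]] = {}
    for k, n_samp in enumerate(config.samples_per_dataset):
        name = f"sim{k + 1}"
        factor = rng.standard_normal(n_samp)
        planted_set = set(planted)
        kept = [g for gi, g in enumerate(genes) if not drop[gi, k]]
        dropped[name] = tuple(g for gi, g in enumerate(genes) if drop[gi, k])

        probeset_ids: list[str] = [f"{target}_ps1"]
        annotation: dict[str, str] = {f"{target}_ps1": target}
        rows: list[np.ndarray] = []
        # target: its own probeset, latent = the factor itself
        t_base = float(rng.lognormal(config.baseline_log_mean, config.baseline_log_sd))
        rows.append(t_base * (1.0 + config.intensity_cv * factor))
        for g in kept:
            beta = config.beta if g in planted_set else 0.0
            noise = rng.standard_normal(n_samp)
            latent = beta * factor + math.sqrt(1.0 - beta * beta) * noise
            base = float(
                rng.lognormal(config.baseline_log_mean, config.baseline_log_sd)
            )
            if g in low_set:
                base = float(rng.uniform(20.0, 80.0))
            for j in range(ppg):
                lat_ps = latent
                if probe_sds[j] > 0:
                    lat_ps = latent + probe_sds[j] * rng.standard_normal(n_samp)
                pid = f"{g}_ps{j + 1}"
                probeset_ids.append(pid)
                annotation[pid] = g
                rows.append(base * (1.0 + config.intensity_cv * lat_ps))
        intensities = np.maximum(np.vstack(rows), 0.0)
        p_present = 1.0 / (
            1.0 + np.exp(-(intensities - config.call_midpoint) / config.call_slope)
        )
        u = rng.random(intensities.shape)
        marginal = rng.random(intensities.shape) < 0.25
        calls = np.where(u < p_present, "P", np.where(marginal, "M", "A")).astype("U1")
        datasets.append(
            ExpressionDataset(
                name=name,
                probeset_ids=tuple(probeset_ids),
                sample_ids=tuple(f"{name}_s{j + 1}" for j in range(n_samp)),
                intensities=intensities,
                calls=calls,
                gene_of=annotation,
            )
        )

    truth = Truth(
        target=target,
        planted_genes=tuple(planted),
        beta_of={g: config.beta for g in planted},
        collapse_winner=winner,
        dropped=dropped,
        low_expr_genes=low_expr,
    )
    return datasets, truth


def write_fixture(datasets, truth: Truth, directory) -> None:
    """Write expression/calls/annotation TSVs per dataset plus a truth TSV.

    Files round-trip exactly through :mod:`coexpr_meta.expression_io`
    and are byte-identical for identical inputs.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        write_expression_matrix(ds, directory / f"{ds.name}_expression.tsv")
        if ds.calls is not None:
            write_calls_matrix(ds, directory / f"{ds.name}_calls.tsv")
        write_annotation(ds.gene_of, directory / f"{ds.name}_annotation.tsv")
    with open(directory / "truth.tsv", "w") as fh:
        fh.write("gene\tbeta\tcollapse_winner\tdropped_in\n")
        for g in truth.planted_genes:
            dropped_in = ",".join(
                name for name, gs in truth.dropped.items() if g in gs
            )
            fh.write(
                f"{g}\t{truth.beta_of[g]!r}\t{truth.collapse_winner[g]}\t{dropped_in}\n"
            )
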