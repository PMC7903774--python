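"""Synthetic multi-omics generator with a scaffold/local-translation causal structure.

The generator emulates a study design in which a postsynaptic scaffold
(Shank3-like) overexpression perturbs the synaptosomal proteome through two
channels: transcription-level changes visible in every RNA layer, and a
polysome-specific translational signal concentrated in up-regulated genes
(local synthesis feeding the postsynaptic density), plus direct scaffolding
recruitment confined to a small interactome subset. Per-gene latent effects
on the log2 scale:

* ``x_g`` — transcription effect, nonzero for a configured fraction of genes,
  Gaussian with SD ``sigma_transcription``;
* ``t_g`` — translation effect, nonzero for a configured fraction, magnitude
  half-Gaussian with SD ``sigma_translation``, sign positive with probability
  ``translational_up_bias`` (the up-regulated asymmetry);
* an interactome flag on a random fraction of genes.

Expected layer fold changes (log2, transgenic vs wild type)::

    whole_tissue  = x_g                                              + noise
    syn_input     = x_g                                              + noise
    syn_polysome  = x_g + alpha_translation * t_g                    + noise
    proteome      = beta_transcription * x_g + alpha_translation * t_g
                    + recruit_effect * [g in interactome]            + noise

Measurement noise is Gaussian per layer on the log2 scale. Replicate-level
negative-binomial count matrices (three replicates per genotype by default)
can be generated from any layer's fold changes so that the quantification
stage has count input to recover them from.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .quantify import FoldChangeTable, LAYERS, TRANSCRIPT_LAYERS

# fixed sub-stream tags so layer streams never collide (see _child_rng)
_STREAM_EFFECTS = 0
_STREAM_INTERACTOME = 1
_STREAM_NOISE = 2
_STREAM_COUNTS = 3


def _default_noise() -> dict[str, float]:
    return {layer: 0.2 for layer in LAYERS}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generative model; defaults are the study-like regime.

    ``n_genes`` defaults to 5000 detected genes/proteins and ``n_replicates``
    to 3 per genotype (three WT/TG pairs). A tenth of genes carry a
    transcription effect and a tenth a translation effect; the translational
    channel is up-biased (0.9) and weighted into the proteome at full
    strength (``alpha_translation=1``) while transcription reaches the
    proteome strongly attenuated (``beta_transcription=0.3`` — a snapshot
    proteome is the net outcome of synthesis and degradation, so
    transcription-level concordance is damped; the attenuation is folded
    into this weight plus noise, not modeled kinetically). Five percent of genes are scaffold interactors gaining an
    additive 0.5 log2 recruitment shift, so recruitment explains only a
    minority of the up-regulated proteome.
    """

    n_genes: int = 5000
    frac_transcriptional: float = 0.10
    frac_translational: float = 0.10
    translational_up_bias: float = 0.9
    sigma_transcription: float = 0.5
    sigma_translation: float = 0.8
    alpha_translation: float = 1.0
    beta_transcription: float = 0.3
    frac_interactome: float = 0.05
    recruit_effect: float = 0.5
    noise_sd_per_layer: Mapping[str, float] = field(default_factory=_default_noise)
    n_replicates: int = 3
    baseline_mean: float = 200.0
    dispersion: float = 10.0  # NB shape r: var = mu + mu^2 / r
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the first offending field."""
        for name in (
            "frac_transcriptional",
            "frac_translational",
            "translational_up_bias",
            "frac_interactome",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("sigma_transcription", "sigma_translation"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_genes < 10:
            raise ConfigurationError(f"n_genes must be >= 10, got {self.n_genes}")
        if self.n_replicates < 2:
            raise ConfigurationError(f"n_replicates must be >= 2, got {self.n_replicates}")
        for layer, sd in dict(self.noise_sd_per_layer).items():
            if layer not in LAYERS:
                raise ConfigurationError(f"noise_sd_per_layer has unknown layer {layer!r}")
            if sd < 0:
                raise ConfigurationError(f"noise_sd_per_layer[{layer!r}] must be >= 0, got {sd}")
        if self.baseline_mean <= 0:
            raise ConfigurationError(f"baseline_mean must be > 0, got {self.baseline_mean}")
        if self.dispersion <= 0:
            raise ConfigurationError(f"dispersion must be > 0, got {self.dispersion}")

    def noise_sd(self, layer: str) -> float:
        return float(dict(self.noise_sd_per_layer).get(layer, 0.0))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["noise_sd_per_layer"] = dict(self.noise_sd_per_layer)
        return d


@dataclass
class SyntheticDataset:
    """Generated tables plus the ground truth that produced them.

    ``ground_truth`` has columns ``x_g`` (transcription effect), ``t_g``
    (translation effect) and ``interactome`` (0/1), indexed by gene id;
    ``fold_changes`` maps each of the four layers to a
    :class:`~synconcord.quantify.FoldChangeTable` over the identical gene
    set; ``counts`` optionally maps layers to replicate count matrices.
    """

    config: SyntheticConfig
    ground_truth: pd.DataFrame
    fold_changes: dict[str, FoldChangeTable]
    counts: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ground_truth.index)

    @property
    def interactome_ids(self) -> list[str]:
        flags = self.ground_truth["interactome"].astype(bool)
        return list(self.ground_truth.index[flags])


def _child_rng(seed: int, stream: int, label: str = "") -> np.random.Generator:
    """Deterministic sub-stream: master seed + stream tag (+ layer label)."""
    entropy = (int(seed), int(stream), zlib.crc32(label.encode("utf-8")))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def simulate_multiomics(
    config: SyntheticConfig, with_counts: bool = False
) -> SyntheticDataset:
    """Draw latent effects and produce fold-change tables for all four layers.

    With ``with_counts=True`` also generates a negative-binomial replicate
    count matrix for each transcriptome layer (the proteome stays intensity
    -based, as in label-free proteomics).
    """
    config.validate()
    n = config.n_genes
    ids = [f"gene{i:05d}" for i in range(n)]

    rng = _child_rng(config.seed, _STREAM_EFFECTS)
    x = np.zeros(n)
    n_trans = round(config.frac_transcriptional * n)
    if n_trans:
        idx = rng.choice(n, size=n_trans, replace=False)
        x[idx] = rng.normal(0.0, config.sigma_transcription, size=n_trans)

    t = np.zeros(n)
    n_transl = round(config.frac_translational * n)
    if n_transl:
        idx = rng.choice(n, size=n_transl, replace=False)
        mag = np.abs(rng.normal(0.0, config.sigma_translation, size=n_transl))
        sign = np.where(rng.random(n_transl) < config.translational_up_bias, 1.0, -1.0)
        t[idx] = sign * mag

    rng_int = _child_rng(config.seed, _STREAM_INTERACTOME)
    inter = np.zeros(n, dtype=bool)
    n_inter = round(config.frac_interactome * n)
    if n_inter:
        inter[rng_int.choice(n, size=n_inter, replace=False)] = True

    expected = {
        "whole_tissue": x,
        "syn_input": x,
        "syn_polysome": x + config.alpha_translation * t,
        "proteome": (
            config.beta_transcription * x
            + config.alpha_translation * t
            + config.recruit_effect * inter.astype(float)
        ),
    }
    fold_changes: dict[str, FoldChangeTable] = {}
    for layer in LAYERS:
        noise_rng = _child_rng(config.seed, _STREAM_NOISE, layer)
        sd = config.noise_sd(layer)
        noise = noise_rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
        fold_changes[layer] = FoldChangeTable(
            layer=layer, values=pd.Series(expected[layer] + noise, index=ids)
        )

    truth = pd.DataFrame(
        {"x_g": x, "t_g": t, "interactome": inter.astype(int)},
        index=pd.Index(ids, name="id"),
    )
    dataset = SyntheticDataset(
        config=config, ground_truth=truth, fold_changes=fold_changes
    )
    if with_counts:
        for layer in TRANSCRIPT_LAYERS:
            dataset.counts[layer] = simulate_counts(
                config, fold_changes[layer], layer
            )
    return dataset


def simulate_counts(
    config: SyntheticConfig, fold_changes: FoldChangeTable, layer: str
) -> pd.DataFrame:
    """Negative-binomial replicate counts realizing a layer's fold changes.

    Per gene g, a lognormal size factor ``s_g`` sets the wild-type mean
    ``baseline_mean * s_g``; the transgenic mean is the wild-type mean times
    ``2**log2fc``. Counts are NB with shape ``dispersion`` (variance
    ``mu + mu^2/dispersion``; the Poisson limit as dispersion grows).
    Columns are named ``<genotype>_<layer>_<replicate>``.
    """
    config.validate()
    if fold_changes.has_duplicates:
        raise InputError("fold-change table has duplicate identifiers")
    fc = fold_changes.values.to_numpy()
    ids = fold_changes.values.index
    rng = _child_rng(config.seed, _STREAM_COUNTS, layer)

    s_g = rng.lognormal(mean=0.0, sigma=0.5, size=len(ids))
    mu_wt = config.baseline_mean * s_g
    mu_tg = mu_wt * np.exp2(fc)

    r = config.dispersion
    cols: dict[str, np.ndarray] = {}
    for geno, mu in (("WT", mu_wt), ("TG", mu_tg)):
        p = r / (r + mu)
        for rep in range(1, config.n_replicates + 1):
            cols[f"{geno}_{layer}_{rep}"] = rng.negative_binomial(r, p)
    return pd.DataFrame(cols, index=pd.Index(ids, name="id"))


def write_fixtures(dataset: SyntheticDataset, directory: str | Path) -> dict:
    """Write the dataset as plain-text fixtures; return a manifest.

    Emits one ``fold_changes_<layer>.tsv`` per layer (``id<TAB>log2fc``),
    ``counts_<layer>.tsv`` for layers with counts, ``ground_truth.tsv`` and
    ``interactome.txt`` (one id per line). The manifest maps each written
    file name to its data row count.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create fixture directory {directory}: {exc}") from exc

    manifest: dict[str, int] = {}
    for layer, table in dataset.fold_changes.items():
        name = f"fold_changes_{layer}.tsv"
        table.to_tsv(directory / name)
        manifest[name] = len(table)
    for layer, counts in dataset.counts.items():
        name = f"counts_{layer}.tsv"
        counts.reset_index().to_csv(directory / name, sep="\t", index=False)
        manifest[name] = len(counts)

    truth_name = "ground_truth.tsv"
    dataset.ground_truth.reset_index().to_csv(
        directory / truth_name, sep="\t", index=False, float_format="%.10g"
    )
    manifest[truth_name] = len(dataset.ground_truth)

    inter_name = "interactome.txt"
    inter = dataset.interactome_ids
    (directory / inter_name).write_text("\n".join(inter) + ("\n" if inter else ""))
    manifest[inter_name] = len(inter)

    (directory / "fixture_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
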