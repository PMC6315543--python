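"""Synthetic expression data with a planted low-rank class signal.

The generator emulates the statistical structure the feature-extraction
method assumes in a merged case/control microarray study:

* a probes x samples matrix ``X = sum_k d_k u_k v_k'`` plus i.i.d. Gaussian
  noise, with orthonormal factors, so each latent factor maps onto one
  principal component of the standardized matrix;
* the control/case difference loads on one *non-leading* factor (the 4th
  by default) — the signal is deliberately buried below stronger
  non-biological sources of variance, as observed in real merged series;
* a small subset of "spiked" probes carries that factor with
  large-magnitude probe scores while all other probes sit near zero on it,
  giving the heavy-tailed score distribution the chi-squared selection
  assumes;
* a many-to-one probe -> gene-symbol annotation, with spiking done at the
  gene level so that the spiked probes collapse to slightly fewer symbols;
* GMT libraries in which a chosen fraction of sets is enriched for the
  spiked genes.

Ground truth (spiked probes/genes, signal component, per-sample factor
values) is returned alongside, so parameter-recovery and null-calibration
experiments can score the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CASE, CONTROL, ExpressionMatrix, GeneSetLibrary, ProbeAnnotation

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_probe_annotation",
    "generate_genesets",
    "write_truth",
    "read_truth",
]


class ConfigurationError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    The defaults mirror the merged-study geometry the pipeline targets:
    5000 probes, 35 control + 25 case samples, six latent factors with the
    class signal on the fourth, and 255 spiked probes.

    Parameters
    ----------
    effect_size
        Class shift on the signal factor's sample values, in units of the
        factor's within-class SD (which is 1 by construction). 0 gives a
        null dataset with no class signal.
    noise_sd
        SD of the i.i.d. Gaussian measurement noise added on top of the
        low-rank structure.
    genes_per_probe
        Target ratio of distinct gene symbols to probes. Values below 1
        make some symbols shared by several probes.
    factor_strength, factor_decay
        Strength of the leading nuisance factor and the geometric ratio
        between consecutive nuisance-factor strengths
        (``d_k = factor_strength * factor_decay**(k-1)`` for every factor
        except the signal one). These dense factors model the strong
        non-biological variance components (tissue composition, batch,
        degradation) that dominate the top PCs of real merged series.
    signal_strength
        Strength of the sparse signal factor. It is set high enough that a
        spiked probe's row variance is dominated by the signal; after
        per-probe standardization the factor's principal component then
        lands between the 3rd and 5th nuisance components, i.e. at index 4
        with the defaults. (Because standardization rescales each probe
        row, the raw strengths and the post-standardization PC order are
        related only indirectly; the defaults were calibrated so the
        effective order is d_1 > d_2 > d_3 > signal > d_5 > d_6 > noise.)
    spike_loading_mean
        Mean of the folded normal from which spiked probes draw their
        (pre-normalization) probe-score magnitude on the signal factor.
    null_loading_sd
        SD of non-spiked probes' scores on the signal factor.
    """

    n_probes: int = 5000
    n_control: int = 35
    n_case: int = 25
    n_factors: int = 6
    signal_pc_index: int = 4
    n_spiked_probes: int = 255
    effect_size: float = 2.0
    noise_sd: float = 1.0
    genes_per_probe: float = 0.95
    seed: int = 0
    factor_strength: float = 400.0
    factor_decay: float = 0.75
    signal_strength: float = 900.0
    spike_loading_mean: float = 8.0
    null_loading_sd: float = 0.05

    def __post_init__(self) -> None:
        if min(self.n_probes, self.n_control, self.n_case, self.n_factors) <= 0:
            raise ConfigurationError("sizes must be positive")
        if not 1 <= self.signal_pc_index <= self.n_factors:
            raise ConfigurationError(
                f"signal_pc_index must be in [1, {self.n_factors}]"
            )
        if not 0 < self.n_spiked_probes < self.n_probes:
            raise ConfigurationError("need 0 < n_spiked_probes < n_probes")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be non-negative")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not 0 < self.genes_per_probe <= 1:
            raise ConfigurationError("genes_per_probe must be in (0, 1]")
        if self.n_factors > min(self.n_probes, self.n_control + self.n_case):
            raise ConfigurationError("n_factors exceeds matrix rank")

    @property
    def n_samples(self) -> int:
        return self.n_control + self.n_case


@dataclass
class GroundTruth:
    """What the generator planted, for scoring recovery."""

    spiked_probe_ids: set[str]
    spiked_gene_symbols: set[str]
    signal_pc_index: int
    per_sample_factor_values: pd.Series = field(repr=False)


def _seeds(config: SimulationConfig) -> tuple:
    """Independent child seeds so annotation / spiking / matrix draws are
    reproducible individually as well as jointly."""
    return tuple(np.random.SeedSequence(config.seed).spawn(3))


def _probe_ids(config: SimulationConfig) -> list[str]:
    width = max(5, len(str(config.n_probes)))
    return [f"PROBE_{i:0{width}d}" for i in range(1, config.n_probes + 1)]


def _sample_ids_labels(config: SimulationConfig) -> tuple[list[str], pd.Series]:
    ids = [f"ctrl_{i:02d}" for i in range(1, config.n_control + 1)]
    ids += [f"case_{i:02d}" for i in range(1, config.n_case + 1)]
    labels = pd.Series(
        [CONTROL] * config.n_control + [CASE] * config.n_case, index=ids
    )
    return ids, labels


def generate_probe_annotation(config: SimulationConfig) -> ProbeAnnotation:
    """Random many-to-one probe -> symbol map.

    ``round(genes_per_probe * n_probes)`` symbols are created; every symbol
    annotates at least one probe and the surplus probes are assigned to
    random symbols, so a fraction of symbols is interrogated by two or more
    probes — the redundancy of real array designs that makes a selected
    probe list collapse to fewer gene symbols.
    """
    ann_seed, _, _ = _seeds(config)
    rng = np.random.default_rng(ann_seed)
    probes = _probe_ids(config)
    n_symbols = max(1, round(config.genes_per_probe * config.n_probes))
    width = max(5, len(str(n_symbols)))
    symbols = [f"GENE{i:0{width}d}" for i in range(1, n_symbols + 1)]
    assignment = list(symbols)
    extra = config.n_probes - n_symbols
    if extra > 0:
        assignment += list(rng.choice(symbols, size=extra, replace=True))
    assignment = list(np.array(assignment)[rng.permutation(config.n_probes)])
    return ProbeAnnotation(dict(zip(probes, assignment)))


def _spiked_probes(
    config: SimulationConfig, annotation: ProbeAnnotation
) -> tuple[list[str], set[str]]:
    """Choose spiked probes gene-by-gene until n_spiked_probes is reached.

    Spiking whole genes (all probes of a symbol move together) mimics real
    differential expression and makes the spiked probes collapse to
    slightly fewer distinct symbols.
    """
    _, spike_seed, _ = _seeds(config)
    rng = np.random.default_rng(spike_seed)
    by_symbol: dict[str, list[str]] = {}
    for probe, symbol in annotation.mapping.items():
        by_symbol.setdefault(symbol, []).append(probe)
    symbols = sorted(by_symbol)
    order = rng.permutation(len(symbols))
    spiked: list[str] = []
    for idx in order:
        for probe in by_symbol[symbols[idx]]:
            spiked.append(probe)
            if len(spiked) == config.n_spiked_probes:
                return spiked, {annotation.mapping[p] for p in spiked}
    raise ConfigurationError("n_spiked_probes exceeds annotated probes")


def _orthonormalize(M: np.ndarray, priority: int) -> np.ndarray:
    """Gram-Schmidt with the ``priority`` column processed first.

    Keeping the signal column's direction intact guarantees the planted
    class shift and spike structure survive orthonormalization; the other
    columns are orthogonalized against it and each other in index order.
    """
    n, k = M.shape
    order = [priority] + [j for j in range(k) if j != priority]
    Q = np.zeros_like(M, dtype=float)
    done: list[int] = []
    for j in order:
        v = M[:, j].astype(float)
        for i in done:
            v = v - (Q[:, i] @ v) * Q[:, i]
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ConfigurationError("degenerate factor draw (zero vector)")
        Q[:, j] = v / norm
        done.append(j)
    return Q


def generate_dataset(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one synthetic study: expression matrix, labels and ground truth.

    The matrix is ``X = sum_k d_k u_k v_k' + eps`` with geometric nuisance
    strengths and a separate signal strength, orthonormal ``u_k`` (probe
    side) and ``v_k`` (sample side), the class shift of ``effect_size``
    planted on the signal factor's sample values before orthonormalization,
    and
    ``eps ~ N(0, noise_sd**2)`` i.i.d. Identical config (including seed)
    gives bit-identical output.
    """
    _, _, mat_seed = _seeds(config)
    rng = np.random.default_rng(mat_seed)
    annotation = generate_probe_annotation(config)
    spiked, spiked_symbols = _spiked_probes(config, annotation)
    probes = _probe_ids(config)
    sample_ids, labels = _sample_ids_labels(config)
    sig = config.signal_pc_index - 1
    n, p = config.n_samples, config.n_probes

    V = rng.standard_normal((n, config.n_factors))
    case_mask = (labels == CASE).to_numpy()
    V[case_mask, sig] += config.effect_size
    factor_values = pd.Series(V[:, sig].copy(), index=sample_ids)
    V = _orthonormalize(V, sig)

    U = rng.standard_normal((p, config.n_factors))
    spiked_mask = np.isin(np.array(probes), np.array(spiked))
    u_sig = rng.normal(0.0, config.null_loading_sd, size=p)
    magnitudes = np.abs(rng.normal(config.spike_loading_mean, 1.0, size=spiked_mask.sum()))
    signs = rng.choice([-1.0, 1.0], size=spiked_mask.sum())
    u_sig[spiked_mask] = magnitudes * signs
    U[:, sig] = u_sig
    U = _orthonormalize(U, sig)

    d = config.factor_strength * config.factor_decay ** np.arange(config.n_factors)
    d[sig] = config.signal_strength
    X = (U * d) @ V.T
    if config.noise_sd > 0:
        X = X + rng.normal(0.0, config.noise_sd, size=(p, n))

    matrix = ExpressionMatrix(
        pd.DataFrame(X, index=probes, columns=sample_ids), labels
    )
    truth = GroundTruth(
        spiked_probe_ids=set(spiked),
        spiked_gene_symbols=spiked_symbols,
        signal_pc_index=config.signal_pc_index,
        per_sample_factor_values=factor_values,
    )
    return matrix, truth


def generate_genesets(
    truth: GroundTruth,
    annotation: ProbeAnnotation,
    n_sets: int = 50,
    enriched_fraction: float = 0.2,
    background_symbols: "set[str] | None" = None,
    seed: int = 0,
    set_size_range: tuple[int, int] = (20, 200),
    enriched_member_fraction: float = 0.5,
) -> GeneSetLibrary:
    """A GMT library in which a fraction of sets is enriched for the
    spiked genes.

    Enriched sets draw ``enriched_member_fraction`` of their members from
    the spiked symbols (without replacement, capped at availability) and
    the rest uniformly from the background; non-enriched sets are uniform
    background draws. Terms are named ``SET_0001`` ... with enriched sets
    flagged in the description.
    """
    if not 0 <= enriched_fraction <= 1:
        raise ConfigurationError("enriched_fraction must be in [0, 1]")
    if n_sets < 0:
        raise ConfigurationError("n_sets must be >= 0")
    lo, hi = set_size_range
    if not 0 < lo <= hi:
        raise ConfigurationError("invalid set_size_range")
    background = (
        set(background_symbols)
        if background_symbols is not None
        else annotation.all_symbols
    )
    background = {s.upper() for s in background}
    if hi > len(background):
        raise ConfigurationError(
            f"max set size {hi} exceeds background of {len(background)} symbols"
        )
    rng = np.random.default_rng(seed)
    bg_list = sorted(background)
    spiked_list = sorted(set(truth.spiked_gene_symbols) & background)
    n_enriched = round(enriched_fraction * n_sets)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(1, n_sets + 1):
        size = int(rng.integers(lo, hi + 1))
        enriched = i <= n_enriched
        members: set[str] = set()
        if enriched and spiked_list:
            take = min(round(enriched_member_fraction * size), len(spiked_list))
            members |= set(rng.choice(spiked_list, size=take, replace=False))
        remaining = size - len(members)
        pool = [s for s in bg_list if s not in members]
        members |= set(rng.choice(pool, size=remaining, replace=False))
        term = f"SET_{i:04d}"
        sets[term] = frozenset(members)
        descriptions[term] = "enriched" if enriched else "background"
    return GeneSetLibrary(sets, descriptions)


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "spiked_probe_ids": sorted(truth.spiked_probe_ids),
        "spiked_gene_symbols": sorted(truth.spiked_gene_symbols),
        "signal_pc_index": truth.signal_pc_index,
        "per_sample_factor_values": truth.per_sample_factor_values.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        spiked_probe_ids=set(payload["spiked_probe_ids"]),
        spiked_gene_symbols=set(payload["spiked_gene_symbols"]),
        signal_pc_index=int(payload["signal_pc_index"]),
        per_sample_factor_values=pd.Series(payload["per_sample_factor_values"]),
    )
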