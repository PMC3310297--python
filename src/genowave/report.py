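"""Batch analysis runs: configuration, TSV tables, figure generation.

A :class:`RunConfig` fully determines the outputs given the inputs: every
stochastic step derives its seed from the single run seed, and every
output file starts with a comment line carrying the config hash and seed,
so identical configs yield byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd

from .complexity import complexity_report
from .plotting import plot_clusters, plot_dot, plot_spiral, plot_walk
from .representation import encode, indicator_matrix, spiral_layout, walk
from .sequence import SymbolSequence, read_fasta, validate_nucleotides
from .synthetic import GeneratorSpec, pseudoperiodic_sequence, pseudorandom_sequence
from .wavelet import coefficient_clusters, short_haar_transform

__all__ = ["RunConfig", "run_report", "walk_table", "cluster_table"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a report run depends on.

    ``inputs`` are FASTA paths; with ``include_controls`` a pseudorandom
    and a pseudoperiodic sequence of ``control_length``/``control_period``
    are appended as reference rows.  Windows and conventions mirror the
    keyword arguments of the underlying functions.
    """

    inputs: tuple[str, ...] = ()
    include_controls: bool = True
    control_length: int = 10_000
    control_period: int = 4
    r_window: int = 10_000
    k_window: int = 100
    d_window: int = 100
    h_window: int = 100
    spread: Literal["variance", "std"] = "variance"
    convention: Literal["CT", "TC"] = "CT"
    wavelet_window: int = 4
    wavelet_signal: Literal["roots", "walk"] = "roots"
    seed: int = 0
    outdir: str = "genowave-out"
    plots: bool = False
    validation_policy: Literal["error", "drop"] = "drop"

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def header(self) -> str:
        return f"# genowave config={self.hash()} seed={self.seed}\n"


def _gather(config: RunConfig) -> list[SymbolSequence]:
    sequences: list[SymbolSequence] = []
    for path in config.inputs:
        for seq in read_fasta(path):
            sequences.append(validate_nucleotides(seq, policy=config.validation_policy))
    if config.include_controls:
        sequences.append(
            pseudorandom_sequence(GeneratorSpec(config.control_length, seed=config.seed))
        )
        sequences.append(
            pseudoperiodic_sequence(
                GeneratorSpec(config.control_length, config.control_period,
                              seed=config.seed + 1)
            )
        )
    if not sequences:
        raise ValueError("no input sequences and controls disabled; nothing to report")
    return sequences


def walk_table(series) -> pd.DataFrame:
    """Walk as a tidy table: n, Re z, Im z, |z|."""
    return pd.DataFrame(
        {
            "n": range(1, len(series) + 1),
            "re_z": series.terms.real,
            "im_z": series.terms.imag,
            "abs_z": series.magnitudes(),
        }
    )


def cluster_table(clusters) -> pd.DataFrame:
    """Clusters as a tidy table: coefficient, real, imag, multiplicity."""
    rows = [
        {"coefficient": label, "real": pt[0], "imag": pt[1], "multiplicity": mult}
        for label, tally in clusters.points.items()
        for pt, mult in tally.items()
    ]
    return pd.DataFrame(rows)


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as handle:
        handle.write(config.header())
        df.to_csv(handle, sep="\t", index=False, float_format="%.10g")


def run_report(config: RunConfig) -> list[Path]:
    """Run the full pipeline and write tables (and, optionally, figures).

    Writes ``complexity.tsv`` (one row per sequence: randomness, K, dot-plot
    dimension, entropy and the windows used), per-sequence walk tables and
    wavelet-cluster tables, and — with ``plots=True`` — dot-plot, spiral,
    walk and cluster figures.  Returns the written paths.  Inputs are read
    and validated before anything is written, so a bad input leaves no
    partial output behind.
    """
    sequences = _gather(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    rows = []
    for i, seq in enumerate(sequences):
        rows.append(
            complexity_report(
                seq,
                r_window=config.r_window,
                k_window=config.k_window,
                d_window=config.d_window,
                h_window=config.h_window,
                spread=config.spread,
                seed=config.seed + i,
            ).as_row()
        )
    table_path = outdir / "complexity.tsv"
    _write_tsv(pd.DataFrame(rows), table_path, config)
    written.append(table_path)

    for seq in sequences:
        stem = (seq.identifier or "seq").replace("/", "_")
        signal = encode(seq, convention=config.convention)
        series = walk(signal)
        walk_path = outdir / f"{stem}.walk.tsv"
        _write_tsv(walk_table(series), walk_path, config)
        written.append(walk_path)

        source = signal if config.wavelet_signal == "roots" else series
        clusters = coefficient_clusters(
            short_haar_transform(source, p=config.wavelet_window)
        )
        cluster_path = outdir / f"{stem}.clusters.tsv"
        _write_tsv(cluster_table(clusters), cluster_path, config)
        written.append(cluster_path)

        if config.plots:
            prefix = seq.prefix(min(len(seq), 200))
            ax = plot_dot(indicator_matrix(prefix))
            dot_path = outdir / f"{stem}.dotplot.png"
            ax.figure.savefig(dot_path, dpi=150)
            fig = plot_spiral(spiral_layout(seq.prefix(min(len(seq), 3752))))
            spiral_path = outdir / f"{stem}.spiral.png"
            fig.savefig(spiral_path, dpi=150)
            ax = plot_walk(series)
            walk_png = outdir / f"{stem}.walk.png"
            ax.figure.savefig(walk_png, dpi=150)
            fig = plot_clusters(clusters)
            clusters_png = outdir / f"{stem}.clusters.png"
            fig.savefig(clusters_png, dpi=150)
            written.extend([dot_path, spiral_path, walk_png, clusters_png])
    return written
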