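"""Unsupervised behavior lexicon from a convolutional autoencoder.

A 1-D convolutional autoencoder compresses fixed-length sensor windows
(M_in x C) into a small latent space R^N (N = 4 for interpolated
sequences, 8 for subsampled windows by default).  The latent cloud is
visualized with a 2-D t-SNE embedding; a kernel-density estimate over
the embedding locates high-density regions, and for each density peak a
representative latent point phi* is taken as the centroid (in the
original latent space) of the peak's member windows.  The trained
decoder maps phi* back to an input-space sequence x* — the pre-image of
the peak — and the collection of decoded x* sequences forms the
behavior lexicon.  Utilities to double-integrate acceleration into
position and to slice IMU axis-plane trajectories support interpreting
the entries as motions.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.stats import gaussian_kde
from sklearn.manifold import TSNE

from . import nn


class ConfigurationError(ValueError):
    pass


def default_latent_dim(sampling: str) -> int:
    """4 latent dimensions for interpolated sequences, 8 for subsampled."""
    return {"interpolate": 4, "subsample": 8}[sampling]


@dataclass
class AEConfig:
    window_length: int = 25         # M_in, rows per input window
    latent_dim: int = 8             # N
    conv_widths: tuple[int, int] = (16, 8)
    pool: int = 5                   # time pooling inside the encoder
    overlap: float = 0.75           # window overlap fraction for windowing
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap <= 0.95:
            raise ConfigurationError("overlap must be in [0, 0.95]")
        if self.window_length % self.pool:
            raise ConfigurationError("window_length must be divisible by pool")


@dataclass
class LatentPoint:
    phi: np.ndarray
    provenance: int | tuple


@dataclass
class DensityPeak:
    phi_star: np.ndarray            # (N,) centroid of member latents
    embedding_xy: np.ndarray        # (2,) peak location in the embedding
    density: float
    member_indices: np.ndarray

    @property
    def member_count(self) -> int:
        return len(self.member_indices)


@dataclass
class LexiconEntry:
    id: str
    phi_star: np.ndarray
    preimage: np.ndarray            # x*: (M_in, C)
    density: float
    member_count: int
    encode_gap: float               # ||encode(x*) - phi*||
    interpretation: str = ""


def window_with_overlap(sequences, window_length: int, overlap: float) -> np.ndarray:
    """Cut each (T, C) sequence into heavily overlapping windows."""
    step = max(1, int(round(window_length * (1.0 - overlap))))
    out = []
    for seq in sequences:
        seq = np.asarray(seq)
        for start in range(0, seq.shape[0] - window_length + 1, step):
            out.append(seq[start:start + window_length])
    return np.stack(out)


class ConvAutoencoder:
    """Convolutional autoencoder model; ``fit()`` returns :class:`AutoencoderResults`."""

    def __init__(self, samples: np.ndarray, config: AEConfig | None = None):
        samples = np.asarray(samples, dtype=float)
        if samples.ndim != 3:
            raise ValueError(f"expected (n, M, C) samples, got {samples.shape}")
        config = config or AEConfig(window_length=samples.shape[1])
        if samples.shape[1] != config.window_length:
            raise ValueError(
                f"sample length {samples.shape[1]} != configured {config.window_length}")
        if config.latent_dim >= samples.shape[1] * samples.shape[2]:
            raise ConfigurationError(
                "latent dimension must be smaller than the flattened input")
        self.samples = samples
        self.config = config

    def _build(self, rng: np.random.Generator):
        cfg = self.config
        C = self.samples.shape[2]
        w1, w2 = cfg.conv_widths
        m_pooled = cfg.window_length // cfg.pool
        encoder: list[nn.Layer] = [
            nn.Conv1D(C, w1, 5, padding="same", rng=rng), nn.ReLU(),
            nn.MaxPool1D(cfg.pool),
            nn.Conv1D(w1, w2, 5, padding="same", rng=rng), nn.ReLU(),
            nn.Flatten(),
            nn.Dense(m_pooled * w2, cfg.latent_dim, rng=rng),
        ]
        decoder: list[nn.Layer] = [
            nn.Dense(cfg.latent_dim, m_pooled * w2, rng=rng), nn.ReLU(),
            nn.Reshape((m_pooled, w2)),
            nn.Conv1D(w2, w1, 5, padding="same", rng=rng), nn.ReLU(),
            nn.Upsample1D(cfg.pool),
            nn.Conv1D(w1, C, 5, padding="same", rng=rng),
        ]
        return nn.Sequential(encoder + decoder), len(encoder)

    def fit(self) -> "AutoencoderResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        net, enc_end = self._build(rng)
        opt = nn.Adam(net, lr=cfg.learning_rate)
        X = self.samples
        history: list[float] = []
        t0 = time.perf_counter()
        for _epoch in range(cfg.epochs):
            order = rng.permutation(len(X))
            losses = []
            for start in range(0, len(X), cfg.batch_size):
                b = order[start:start + cfg.batch_size]
                recon = net.forward(X[b])
                loss, dpred = nn.mse_loss(recon, X[b])
                if not np.isfinite(loss):
                    raise RuntimeError(f"non-finite loss at epoch {_epoch}")
                net.backward(dpred)
                opt.step()
                losses.append(loss)
            history.append(float(np.mean(losses)))
        return AutoencoderResults(model=self, network=net, encoder_end=enc_end,
                                  history=history,
                                  fit_seconds=time.perf_counter() - t0)


@dataclass
class AutoencoderResults:
    model: ConvAutoencoder
    network: nn.Sequential
    encoder_end: int
    history: list[float]
    fit_seconds: float

    @property
    def latent_dim(self) -> int:
        return self.model.config.latent_dim

    @property
    def final_loss(self) -> float:
        return self.history[-1]

    def encode(self, samples: np.ndarray) -> np.ndarray:
        """Map (n, M_in, C) windows to (n, N) latent vectors."""
        x = np.asarray(samples, dtype=float)
        if x.ndim != 3 or x.shape[1:] != self.model.samples.shape[1:]:
            raise ValueError(
                f"sample shape {x.shape[1:]} != training shape "
                f"{self.model.samples.shape[1:]}")
        for layer in self.network.layers[:self.encoder_end]:
            x = layer.forward(x)
        return x

    def decode(self, phi: np.ndarray) -> np.ndarray:
        """Map latent vectors back to sequences; (N,) -> (M_in, C)."""
        phi = np.asarray(phi, dtype=float)
        single = phi.ndim == 1
        x = phi[None, :] if single else phi
        if x.shape[1] != self.latent_dim:
            raise ValueError(f"latent length {x.shape[1]} != N={self.latent_dim}")
        for layer in self.network.layers[self.encoder_end:]:
            x = layer.forward(x)
        return x[0] if single else x

    def reconstruct(self, samples: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(samples))

    def summary(self) -> str:
        cfg = self.model.config
        var = float(self.model.samples.var())
        lines = [
            "Convolutional autoencoder results",
            "=================================",
            f"windows               {self.model.samples.shape[0]}",
            f"window shape          {cfg.window_length} x {self.model.samples.shape[2]}",
            f"latent dimension      {cfg.latent_dim}",
            f"epochs                {len(self.history)}",
            f"final train MSE       {self.final_loss:.5f}",
            f"data variance         {var:.5f}",
            f"MSE / variance        {self.final_loss / var:.4f}",
            f"fit wall time         {self.fit_seconds:.1f} s",
        ]
        return "\n".join(lines)


def train_autoencoder(samples: np.ndarray, config: AEConfig | None = None):
    """Functional wrapper: returns (results, per-epoch loss history)."""
    results = ConvAutoencoder(samples, config).fit()
    return results, results.history


def encode(results: AutoencoderResults, samples: np.ndarray) -> list[LatentPoint]:
    lat = results.encode(samples)
    return [LatentPoint(phi=lat[i], provenance=i) for i in range(len(lat))]


def decode(results: AutoencoderResults, phi: np.ndarray) -> np.ndarray:
    return results.decode(phi)


def embed_2d(latents: np.ndarray, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """2-D t-SNE embedding of the latent cloud; reproducible given seed."""
    latents = np.asarray(latents, dtype=float)
    n = latents.shape[0]
    if n < 10:
        raise ValueError("need at least 10 latent points")
    if perplexity >= n:
        raise ValueError(f"perplexity {perplexity} requires more than {n} points")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    return tsne.fit_transform(latents)


def find_density_peaks(latents: np.ndarray, embedding: np.ndarray, n_peaks: int,
                       min_separation: float | None = None,
                       bandwidth=None) -> list[DensityPeak]:
    """Greedy density-peak selection on the 2-D embedding.

    A Gaussian KDE (Scott's rule by default) scores every embedded point;
    points are visited in decreasing density and accepted as peaks while
    at least ``min_separation`` (default: 10% of the embedding bounding-box
    diagonal) from every accepted peak.  Each peak's members are the
    points within its basin radius — half the minimum inter-peak distance
    (all points, for a single peak).  phi* is the member centroid in the
    original latent space.
    """
    latents = np.asarray(latents, dtype=float)
    embedding = np.asarray(embedding, dtype=float)
    if len(latents) != len(embedding):
        raise ValueError("latents and embedding must align")
    try:
        kde = gaussian_kde(embedding.T, bw_method=bandwidth)
        density = kde(embedding.T)
    except np.linalg.LinAlgError:
        # degenerate cloud (e.g. all points identical): one peak, everything in it
        density = np.full(len(embedding), float(len(embedding)))
    span = embedding.max(axis=0) - embedding.min(axis=0)
    diagonal = float(np.hypot(*span))
    if min_separation is None:
        min_separation = 0.1 * diagonal
    # coincident points can never be separate peaks
    min_separation = max(min_separation, 1e-12)
    order = np.argsort(density)[::-1]
    peak_idx: list[int] = []
    for i in order:
        if len(peak_idx) == n_peaks:
            break
        if all(np.linalg.norm(embedding[i] - embedding[j]) >= min_separation
               for j in peak_idx):
            peak_idx.append(int(i))
    if len(peak_idx) < n_peaks:
        warnings.warn(f"only {len(peak_idx)} density peaks found "
                      f"(requested {n_peaks})")
    if len(peak_idx) > 1:
        dists = [np.linalg.norm(embedding[a] - embedding[b])
                 for a in peak_idx for b in peak_idx if a != b]
        basin_radius = 0.5 * min(dists)
    else:
        basin_radius = np.inf
    peaks = []
    for i in peak_idx:
        d = np.linalg.norm(embedding - embedding[i], axis=1)
        members = np.flatnonzero(d <= basin_radius)
        peaks.append(DensityPeak(phi_star=latents[members].mean(axis=0),
                                 embedding_xy=embedding[i],
                                 density=float(density[i]),
                                 member_indices=members))
    peaks.sort(key=lambda p: -p.density)
    return peaks


def build_lexicon(results: AutoencoderResults, latents: np.ndarray,
                  embedding: np.ndarray, n_peaks: int,
                  min_separation: float | None = None,
                  bandwidth=None) -> list[LexiconEntry]:
    """Decode each density peak's phi* into its pre-image sequence x*."""
    peaks = find_density_peaks(latents, embedding, n_peaks,
                               min_separation=min_separation, bandwidth=bandwidth)
    entries = []
    for rank, peak in enumerate(peaks, start=1):
        x_star = results.decode(peak.phi_star)
        gap = float(np.linalg.norm(results.encode(x_star[None])[0] - peak.phi_star))
        entries.append(LexiconEntry(id=f"x{rank}", phi_star=peak.phi_star,
                                    preimage=x_star, density=peak.density,
                                    member_count=peak.member_count,
                                    encode_gap=gap))
    return entries


def export_lexicon(entries: list[LexiconEntry], directory: str | Path) -> None:
    """JSON summary plus one CSV of x* per entry."""
    import pandas as pd
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = [{"id": e.id, "phi_star": e.phi_star.tolist(), "density": e.density,
             "member_count": e.member_count, "encode_gap": e.encode_gap,
             "interpretation": e.interpretation} for e in entries]
    (directory / "lexicon.json").write_text(json.dumps(meta, indent=2))
    for e in entries:
        pd.DataFrame(e.preimage).to_csv(directory / f"{e.id}.csv", index=False)


def double_integrate(acceleration: np.ndarray, dt: float) -> np.ndarray:
    """Position from acceleration: cumulative trapezoidal integration twice,
    zero initial velocity and position.  Output length equals input length."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    a = np.asarray(acceleration, dtype=float)
    velocity = cumulative_trapezoid(a, dx=dt, axis=0, initial=0.0)
    return cumulative_trapezoid(velocity, dx=dt, axis=0, initial=0.0)


_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def axis_plane_trajectory(imu_sequence: np.ndarray, axes: tuple[str, str]) -> np.ndarray:
    """Time-ordered (a1, a2) points for manifold-style plane plots."""
    seq = np.asarray(imu_sequence, dtype=float)
    try:
        cols = [_AXIS_INDEX[a] for a in axes]
    except KeyError as exc:
        raise ValueError(f"unknown axis name {exc.args[0]!r}; use x, y, z") from None
    if seq.ndim != 2 or seq.shape[1] <= max(cols):
        raise ValueError("sequence lacks the requested axes")
    return seq[:, cols]
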