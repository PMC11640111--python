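"""Canned study experiments at desk scale.

These routines wire the full pipeline together under the default study
conditions — a 20-dog synthetic cohort running the 50-state protocol —
and expose the headline quantities: classifier accuracy against chance
on the easy 10-state variants, the audio-fusion comparison on the
noise-distraction states, and planted-motif recovery by the lexicon.
Every routine is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np

from .convlstm import ConvLSTMClassifier, ConvLSTMConfig
from .evaluation import confusion, macro_report, prediction_flow, preliminary_state_subset
from .kpca import KPCARidgeClassifier, gamma_grid_search
from .lexicon import AEConfig, ConvAutoencoder, build_lexicon, embed_2d
from .preprocess import build_dataset_variant, split_train_test, znormalize_session
from .synthetic import CohortConfig, generate_cohort

#: ten protocol states including the noise-distraction pairs whose IMU
#: motifs coincide and which only the audio channel can tell apart
NOISE_RICH_SUBSET = [
    "Idle", "Heel walking", "Trot on leash", "Rolly toy chase",
    "Noise can shake", "Noise can seen", "Vacuum on-On leash",
    "Vacuum off-On leash", "Dog on table", "Fan passes",
]

GAMMA_GRID = np.logspace(-5, -1, 5)


def build_study_cohort(n_dogs: int = 20, master_seed: int = 0):
    """Z-normalized sessions for the default 50-state study cohort."""
    cfg = CohortConfig(n_dogs=n_dogs, master_seed=master_seed)
    return [znormalize_session(s)[0] for s in generate_cohort(cfg)]


def _select_gamma(Xtr, ytr, seed: int) -> float:
    """Validation-based gamma selection on a log grid (the method's one
    main hyperparameter)."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(ytr))
    n_val = max(len(ytr) // 5, 1)
    va, tr = idx[:n_val], idx[n_val:]
    best, _ = gamma_grid_search(Xtr[tr], ytr[tr], Xtr[va], ytr[va],
                                gammas=GAMMA_GRID)
    return best


def kpca_experiment(sessions, subset, sampling: str, fusion: str, seed: int = 0):
    """Fit KPCA+Ridge on one 10-state variant; returns metrics dict."""
    variant = build_dataset_variant(sessions, sampling, 10, fusion, subset)
    split = split_train_test(variant, 0.7, seed, "event")
    Xtr, ytr = split.arrays("train")
    Xte, yte = split.arrays("test")
    gamma = _select_gamma(Xtr, ytr, seed)
    res = KPCARidgeClassifier(Xtr, ytr, gamma=gamma).fit()
    pred = res.predict(Xte)
    vocab = split.vocabulary
    cm = confusion([vocab[i] for i in yte], [vocab[i] for i in pred], vocab)
    rep = macro_report(cm)
    return {"accuracy": rep.accuracy, "macro_f1": rep.macro_f1,
            "macro_precision": rep.macro_precision,
            "macro_recall": rep.macro_recall, "gamma": gamma,
            "n_train": len(ytr), "n_test": len(yte), "confusion": cm}


def convlstm_experiment(sessions, subset, fusion: str = "imu", seed: int = 0,
                        epochs: int = 20):
    """Train the Conv-LSTM on the subsampled 10-state variant."""
    variant = build_dataset_variant(sessions, "subsample", 10, fusion, subset)
    split = split_train_test(variant, 0.7, seed, "event")
    Xtr, ytr = split.arrays("train")
    Xte, yte = split.arrays("test")
    cfg = ConvLSTMConfig(dense_out=10, epochs=epochs, seed=seed,
                         early_stopping_patience=None)
    res = ConvLSTMClassifier(Xtr, ytr, split.vocabulary, cfg).fit()
    pred = res.predict_indices(Xte)
    vocab = split.vocabulary
    cm = confusion([vocab[i] for i in yte], [vocab[i] for i in pred], vocab)
    rep = macro_report(cm)
    return {"accuracy": rep.accuracy, "macro_f1": rep.macro_f1,
            "macro_precision": rep.macro_precision,
            "macro_recall": rep.macro_recall,
            "n_train": len(ytr), "n_test": len(yte),
            "history": res.history, "confusion": cm}


def audio_fusion_comparison(sessions, seed: int = 0, n_repeats: int = 5):
    """KPCA accuracy with and without the audio channel on the
    noise-distraction-rich 10-state interpolated variant.

    A single 70/30 split leaves only ~60 test events, so the comparison
    is averaged over ``n_repeats`` independent splits to give the fusion
    contrast adequate power.
    """
    out = {}
    for fusion in ("imu", "imu-audio"):
        base = (seed % 2 ** 20) * n_repeats
        accs = [kpca_experiment(sessions, NOISE_RICH_SUBSET, "interpolate",
                                fusion, seed=base + r)["accuracy"]
                for r in range(n_repeats)]
        out[fusion] = {"accuracy": float(np.mean(accs)),
                       "per_split": accs, "n_repeats": n_repeats}
    return out


def planted_motif_catalogue():
    """Three distinct oscillatory motion motifs as 25 x 3 IMU windows."""
    t = np.arange(25) / 100.0
    motifs = []
    for f, amp, base in [(2.0, 1.0, 0.0), (6.0, 0.8, 0.5), (0.5, 1.2, -0.5)]:
        motifs.append(np.stack(
            [base + amp * np.sin(2 * np.pi * f * t + 2 * np.pi * c / 3)
             for c in range(3)], axis=1))
    return motifs


def lexicon_recovery_experiment(seed: int = 0, n_copies: int = 150,
                                noise_sd: float = 0.05, epochs: int = 50):
    """Train the autoencoder on noisy copies of 3 planted motifs and count
    how many distinct motifs the decoded density-peak pre-images recover
    by nearest mean-squared-error assignment."""
    rng = np.random.default_rng(seed)
    motifs = planted_motif_catalogue()
    X = np.concatenate([m + rng.normal(0, noise_sd, (n_copies,) + m.shape)
                        for m in motifs])
    cfg = AEConfig(window_length=25, latent_dim=8, epochs=epochs, seed=seed)
    res = ConvAutoencoder(X, cfg).fit()
    latents = res.encode(X)
    embedding = embed_2d(latents, perplexity=30.0, seed=seed)
    entries = build_lexicon(res, latents, embedding, n_peaks=3)
    nearest = [int(np.argmin([((e.preimage - m) ** 2).mean() for m in motifs]))
               for e in entries]
    return {"n_entries": len(entries),
            "n_distinct_recovered": len(set(nearest)),
            "assignments": nearest,
            "final_mse": res.final_loss,
            "data_variance": float(X.var()),
            "entries": entries}


def state_flow_experiment(sessions, seed: int = 0, theta: float = 0.30):
    """50-state KPCA run and the resulting most-common-prediction map."""
    variant = build_dataset_variant(sessions, "interpolate", 50, "imu")
    split = split_train_test(variant, 0.7, seed, "event")
    Xtr, ytr = split.arrays("train")
    Xte, yte = split.arrays("test")
    res = KPCARidgeClassifier(Xtr, ytr, gamma=1e-3).fit()
    pred = res.predict(Xte)
    vocab = split.vocabulary
    cm = confusion([vocab[i] for i in yte], [vocab[i] for i in pred], vocab)
    flow = prediction_flow(cm, theta)
    return {"accuracy": macro_report(cm).accuracy,
            "n_null_states": len(flow.null_states), "flow": flow,
            "confusion": cm}


def easy_state_subset(sessions, seed: int = 0) -> list[str]:
    """The 10 most distinguishable states per a preliminary KPCA run."""
    return preliminary_state_subset(sessions, 10, gamma=1e-3, seed=seed)
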