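"""Parameter-recovery benchmarks on synthetic data.

Each routine generates a two-condition synthetic dataset with known
ground truth, runs the corresponding analysis chain exactly as a user
would, and returns both the recovered and the true quantities.  They are
shared by the acceptance test-suite and the ``scripts/acceptance.py``
runner.  Problem sizes default to the study design of the assays they
emulate (20 images, 12 cells or 6 arrays per condition, ~100 EM synapses
per genotype).
"""

from __future__ import annotations

import numpy as np

from . import em, imaging, mea, minis, synthetic


def _field_density(seed: int, density_factor: float) -> tuple[float, float]:
    """Measured and true synapse density (per µm dendrite) for one field."""
    params = synthetic.ImagingSimParams(
        seed=seed, n_neurites=5,
        condition_effects={"sim": {"density": density_factor, "intensity": 1.0}},
    )
    fov, truth = synthetic.gen_neuron_field(params, "sim")
    px = fov.pixel_size
    nm = imaging.neurite_mask(fov.channels["MAP2"], px, scale_um=0.5)
    pre = imaging.detect_puncta(fov.channels["pre"], px, threshold_spec="otsu")
    post = imaging.detect_puncta(fov.channels["post"], px, threshold_spec="otsu")
    post = imaging.filter_on_neurites(post, nm)
    table = imaging.tally_synapses(pre, post)
    measured = imaging.synapse_density(table, nm)
    return measured, truth.n_pairs / truth.skeleton_length_um


def recover_synapse_density_ratios(
    density_factors: tuple[float, ...] = (1.0, 0.75, 0.66),
    n_images: int = 20,
    base_seed: int = 0,
) -> dict:
    """Recover known between-condition synapse-density factors.

    One control condition (factor 1) is imaged once and compared against
    an independent test condition per factor; every condition comprises
    ``n_images`` independent fields and the estimate is the ratio of
    condition-mean measured densities.
    """
    ctrl = [_field_density(base_seed + i, 1.0)[0] for i in range(n_images)]
    out = {"n_images": n_images, "control_mean_per_um": float(np.mean(ctrl)),
           "ratios": {}}
    for k, factor in enumerate(density_factors):
        test = [_field_density(base_seed + 10_000 * (k + 1) + i, factor)[0]
                for i in range(n_images)]
        out["ratios"][factor] = float(np.mean(test) / np.mean(ctrl))
    return out


def recover_mini_statistics(
    rate_control: float = 1.0,
    rate_test: float = 0.42,
    n_traces: int = 12,
    base_seed: int = 0,
) -> dict:
    """Recover the mEPSC frequency ratio and mean amplitudes.

    Each condition contributes ``n_traces`` two-minute recordings;
    per-cell frequencies are accepted-event counts over duration, and the
    reported ratio compares condition means, mirroring the per-cell
    analysis of real recordings.
    """
    out = {"true_ratio": rate_test / rate_control, "n_traces": n_traces}
    freqs, amp_err = {}, {}
    for label, rate, offset in (("control", rate_control, 0),
                                ("test", rate_test, 50_000)):
        cell_freqs, est_amps, true_amps = [], [], []
        for i in range(n_traces):
            p = synthetic.TraceSimParams(event_rate=rate,
                                         seed=base_seed + offset + i)
            trace, truth = synthetic.gen_current_trace(p)
            _, summary = minis.analyse_trace(trace)
            cell_freqs.append(summary.frequency_hz)
            est_amps.append(summary.mean_amplitude_pa)
            true_amps.append(truth["amplitude_pA"].mean())
        freqs[label] = float(np.mean(cell_freqs))
        amp_err[label] = float(np.nanmean(est_amps) / np.mean(true_amps) - 1.0)
    out["estimated_ratio"] = freqs["test"] / freqs["control"]
    out["control_frequency_hz"] = freqs["control"]
    out["amplitude_rel_error_control"] = amp_err["control"]
    out["amplitude_rel_error_test"] = amp_err["test"]
    return out


def recover_network_interval(
    period_s: float, n_arrays: int = 6, duration_s: float = 600.0,
    base_seed: int = 0,
) -> dict:
    """Recover the mean network-burst interval of arrays bursting with a
    known mean period, through spike-raster burst/network-burst analysis."""
    est, true = [], []
    for i in range(n_arrays):
        p = synthetic.RasterSimParams(burst_rate=1.0 / period_s,
                                      duration=duration_s,
                                      seed=base_seed + i)
        trains, truth = synthetic.gen_spike_raster(p)
        active, _ = mea.select_active_channels(trains, p.duration)
        bursts = [b for tr in active for b in mea.detect_bursts(tr)]
        nbs = mea.detect_network_bursts(bursts, n_active_channels=len(active))
        m = mea.network_metrics(nbs)
        est.append(m["mean_interburst_interval_s"])
        true.append(truth["mean_interval_s"])
    return {
        "true_period_s": period_s,
        "true_mean_interval_s": float(np.mean(true)),
        "estimated_mean_interval_s": float(np.mean(est)),
        "n_arrays": n_arrays,
    }


def recover_em_ratios(
    density_factor: float = 0.70,
    docked_factor: float = 0.5,
    n_per_group: int = 100,
    base_seed: int = 0,
) -> dict:
    """Recover SV-density and docked-count ratios between two genotypes
    generated with known multiplicative factors."""
    base_density = 120.0
    base_docked = 0.30
    groups, truth_docked = {}, {}
    for label, dens, dock, offset in (
        ("wt", base_density, base_docked, 0),
        ("ko", base_density * density_factor, base_docked * docked_factor, 30_000),
    ):
        anns, true_dock = [], []
        for i in range(n_per_group):
            p = synthetic.VesicleSimParams(vesicle_density=dens,
                                           docked_fraction=dock,
                                           seed=base_seed + offset + i)
            ann, truth = synthetic.gen_vesicle_annotation(p, f"{label}{i}")
            anns.append(ann)
            true_dock.append(truth["docked"].sum())
        groups[label] = anns
        truth_docked[label] = float(np.mean(true_dock))
    per_syn, gsum = em.summarize_em(groups)
    dens = gsum.set_index("group")["mean_sv_density"]
    dock = gsum.set_index("group")["mean_docked"]
    return {
        "true_density_factor": density_factor,
        "estimated_density_ratio": float(dens["ko"] / dens["wt"]),
        "true_docked_ratio": truth_docked["ko"] / truth_docked["wt"],
        "estimated_docked_ratio": float(dock["ko"] / dock["wt"]),
        "n_per_group": n_per_group,
    }


def type_one_error_rates(reps: int = 10_000, n: int = 20, seed: int = 0) -> dict:
    """Empirical type-I error of the implemented tests at alpha = 0.05.

    Null replicates are standard-normal groups of size ``n``.  The t-type
    tests and one-way ANOVA are evaluated vectorised through the same
    SciPy routines ``compare_groups`` dispatches to; the Wilcoxon
    signed-rank uses the exact small-sample path; the Tukey family-wise
    rate uses the independent SciPy implementation that the test-suite
    proves equal to the package's own Tukey p-values.
    """
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (reps, n))
    b = rng.normal(0, 1, (reps, n))
    c = rng.normal(0, 1, (reps, n))
    alpha = 0.05
    rates = {
        "unpaired_t": float((sps.ttest_ind(a, b, axis=1).pvalue < alpha).mean()),
        "paired_t": float((sps.ttest_rel(a, b, axis=1).pvalue < alpha).mean()),
        "one_sample_t": float((sps.ttest_1samp(a, 0.0, axis=1).pvalue < alpha).mean()),
        "anova": float((sps.f_oneway(a, b, c, axis=1).pvalue < alpha).mean()),
    }
    wil = np.empty(reps)
    for i in range(reps):
        wil[i] = sps.wilcoxon(a[i], method="exact").pvalue
    rates["wilcoxon"] = float((wil < alpha).mean())
    # Tukey family-wise rate: any pair rejects iff the largest studentized
    # range statistic exceeds its alpha critical value
    k, df = 3, 3 * n - 3
    groups = np.stack([a, b, c])                      # (k, reps, n)
    means = groups.mean(axis=2)
    mse = groups.var(axis=2, ddof=1).mean(axis=0)
    q_max = (means.max(axis=0) - means.min(axis=0)) / np.sqrt(mse / n)
    crit = sps.studentized_range.ppf(1 - alpha, k, df)
    rates["tukey_familywise"] = float((q_max > crit).mean())
    return rates
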