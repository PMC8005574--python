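"""Self-contained reference computations used by the validation suite.

Each function recomputes one headline quantity from scratch by running the
package's own pipeline on synthetic inputs; nothing is cached or looked up.
"""

from __future__ import annotations

import numpy as np

from . import clinical, pipeline, spectral, synthetic


def null_cohort_grand_median_accuracy(seed: int = 0, n_subjects: int = 20,
                                      duration_s: float = 180.0,
                                      fs: float = 1000.0,
                                      log=lambda *_: None) -> float:
    """Grand median decoding accuracy on a cohort with zero medication effect.

    Runs the complete per-subject pipeline — signal generation, epoch
    rejection, lowpass, snippeting, Welch band powers, Bayesian box-constraint
    search and unshuffled 10-fold cross-validation — and returns the median
    of the per-subject median fold accuracies.
    """
    config = pipeline.PipelineConfig(
        n_subjects=n_subjects, duration_s=duration_s, sampling_rate_hz=fs,
        seed=seed, optimize_c=True)
    cohort = synthetic.generate_cohort(pipeline.cohort_from_config(config))
    medians = []
    for spec in cohort.spec.subject_specs:
        table = spectral.build_feature_table(
            cohort.subject_recordings(spec.subject_id), config.spectral)
        result, _ = pipeline.decode_subject(table, config, spec.subject_id)
        medians.append(result.median_accuracy)
        log(f"{spec.subject_id}: median accuracy {result.median_accuracy:.3f}")
    return float(np.median(medians))


def welch_grid_spacing(fs: float = 1000.0, snippet_len_s: float = 5.0,
                       seed: int = 0) -> float:
    """Bin spacing of the pipeline's Welch spectrum on one 5 s snippet."""
    rng = np.random.default_rng(seed)
    snippet = spectral.normalize_snippet(
        rng.standard_normal(int(snippet_len_s * fs)))
    spectrum = spectral.welch_psd(snippet, fs)
    spacings = np.diff(spectrum.frequencies_hz)
    if not np.allclose(spacings, spacings[0]):
        raise AssertionError("frequency grid is not uniform")
    return float(spacings[0])


def factor1_item_count() -> int:
    """Items assigned to motor factor 1 by the default factor structure."""
    structure = clinical.default_factor_structure()
    sizes = structure.factor_sizes()
    if sizes != clinical.EXPECTED_FACTOR_SIZES:
        raise AssertionError(f"unexpected factor sizes {sizes}")
    return sizes[0]
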