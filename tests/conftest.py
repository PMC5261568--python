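import numpy as np
import pytest

from ftirmark import (ScatterModel, SpectrumSet, StudyDesign, ThresholdRule,
                      default_band_library, default_grid, emsc_correct,
                      extract_window, pls1_fit, pls_loocv,
                      savgol_second_derivative, synth_dataset)


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def library():
    return default_band_library()


@pytest.fixture(scope="session")
def study_dataset():
    """The default synthetic study dataset (default design, seed 0)."""
    return synth_dataset(StudyDesign(seed=0))


@pytest.fixture(scope="session")
def preprocessed(study_dataset):
    """EMSC (calibration-mean reference) -> 2nd derivative -> Amide I
    window of the default dataset; returns (windowed set, reference)."""
    cal = study_dataset.subset(np.isin(
        study_dataset.splits, ["pca_cal", "pls_cal", "internal_pred"]))
    reference = cal.mean_spectrum()
    corrected = emsc_correct(study_dataset, reference=reference).corrected
    windowed = extract_window(savgol_second_derivative(corrected, 9, 3),
                              1710, 1585)
    return windowed, reference


@pytest.fixture(scope="session")
def trained_pls(preprocessed):
    """LOOCV-selected PLS1 fitted on the pls_cal split."""
    windowed, _ = preprocessed
    pls_set = windowed.select_split("pls_cal")
    rule = ThresholdRule()
    y = rule.encode(pls_set.labels)
    cv = pls_loocv(pls_set, y, max_factors=10)
    model = pls1_fit(pls_set, y, cv.chosen, thresholds=rule)
    return model, cv


def pure_class_mean(library, grid, name):
    """Noise- and scatter-free band sum of one class, as a 1-row set."""
    return SpectrumSet(grid, library[name].pure_spectrum(grid)[None, :])


@pytest.fixture(scope="session")
def zero_scatter():
    return ScatterModel.none()
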