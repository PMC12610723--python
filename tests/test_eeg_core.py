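"""EDF I/O and preprocessing: filtering, ICA artifact removal, resampling."""

import numpy as np
import pytest

from eegtransfer import (ChannelNotFoundError, DomainDataset, EEGEpoch,
                         FATIGUE3, FormatError, ParameterError, SLEEP5,
                         bandpass_filter, load_epoch_text, load_labels,
                         read_edf, remove_artifacts_ica, resample,
                         save_epoch_text, save_labels, write_edf)
from eegtransfer.eeg_core import load_epoch_npz, save_epoch_npz
from eegtransfer.synth import SOURCE_SIGNATURES, generate_epoch, inject_artifact


def sine_dataset(freq, rate=200.0, length_s=30.0, n_epochs=3, amp=30.0):
    t = np.arange(int(rate * length_s)) / rate
    eps = [EEGEpoch(amp * np.sin(2 * np.pi * freq * t + 0.31 * k), rate, "O1")
           for k in range(n_epochs)]
    return DomainDataset("target", eps, FATIGUE3, np.zeros(n_epochs, int))


def rms(x):
    return float(np.sqrt(np.mean(np.asarray(x) ** 2)))


# ------------------------------------------------------------------- types

def test_epoch_invariants():
    with pytest.raises(ParameterError):
        EEGEpoch(np.array([1.0, np.inf]), 100.0)
    with pytest.raises(ParameterError):
        EEGEpoch(np.zeros(10), -1.0)
    ep = EEGEpoch(np.zeros(3000), 100.0, "O1")
    assert ep.length_s == 30.0 and ep.n_samples == 3000


def test_dataset_invariants():
    eps = [EEGEpoch(np.zeros(100), 100.0)] * 3
    with pytest.raises(ParameterError):
        DomainDataset("elsewhere", eps, SLEEP5, [0, 1, 2])
    with pytest.raises(ParameterError):
        DomainDataset("source", eps, SLEEP5, [0, 1])       # length mismatch
    with pytest.raises(ParameterError):
        DomainDataset("source", eps, SLEEP5, [0, 1, 7])    # index range
    mixed = eps + [EEGEpoch(np.zeros(50), 100.0)]
    with pytest.raises(ParameterError):
        DomainDataset("source", mixed, SLEEP5, None)


def test_label_scheme_sizes():
    assert SLEEP5.n_classes == 5 and SLEEP5.classes[0] == "W"
    assert FATIGUE3.n_classes == 3 and FATIGUE3.classes == (
        "Awake", "Mild Fatigue", "Severe Fatigue")


# --------------------------------------------------------------------- EDF

@pytest.mark.parametrize("length_s,expected_epochs", [(90, 3), (95, 3)])
def test_read_edf_cuts_30s_epochs(tmp_path, length_s, expected_epochs):
    """90 s → 3 epochs; 95 s → 3 epochs with the 5 s remainder dropped."""
    rate = 100.0
    t = np.arange(int(rate * length_s)) / rate
    sig = 40 * np.sin(2 * np.pi * 9 * t)
    # write as 5 s records so the file length is not a multiple of 30 s
    n_rec = int(rate * 5)
    records = [EEGEpoch(sig[k * n_rec:(k + 1) * n_rec], rate, "Fpz-Cz")
               for k in range(len(sig) // n_rec)]
    path = tmp_path / "rec.edf"
    write_edf(path, DomainDataset("source", records, SLEEP5, None))
    ds = read_edf(path, "Fpz-Cz")
    assert len(ds) == expected_epochs
    assert ds.epochs[0].n_samples == 3000
    assert ds.labels is None


def test_read_edf_missing_channel(tmp_path):
    ds = sine_dataset(10, rate=100)
    path = tmp_path / "rec.edf"
    write_edf(path, ds)
    with pytest.raises(ChannelNotFoundError):
        read_edf(path, "O9")


def test_read_edf_malformed(tmp_path):
    path = tmp_path / "junk.edf"
    path.write_bytes(b"this is not an EDF header at all" * 20)
    with pytest.raises(FormatError):
        read_edf(path, "O1")


def test_edf_roundtrip_within_quantization(tmp_path):
    ds = sine_dataset(10, rate=100, amp=80.0)
    path = tmp_path / "rt.edf"
    write_edf(path, ds)
    back = read_edf(path, "O1", domain="target", scheme=FATIGUE3)
    orig = ds.as_matrix()
    quant = (orig.max() - orig.min()) / 65535
    assert np.abs(back.as_matrix() - orig).max() <= quant * 1.01


# ---------------------------------------------------------------- bandpass

def test_bandpass_attenuates_out_of_band():
    out = bandpass_filter(sine_dataset(60.0))
    assert rms(out.as_matrix()) < 0.05 * rms(sine_dataset(60.0).as_matrix())


def test_bandpass_passes_in_band():
    ds = sine_dataset(10.0)
    out = bandpass_filter(ds)
    assert abs(rms(out.as_matrix()) - rms(ds.as_matrix())) < 0.1 * rms(ds.as_matrix())


def test_bandpass_zero_in_zero_out():
    eps = [EEGEpoch(np.zeros(6000), 200.0, "O1")]
    out = bandpass_filter(DomainDataset("target", eps, FATIGUE3, [0]))
    assert np.all(out.as_matrix() == 0)


def test_bandpass_idempotent():
    ds = generate_domain_pair_for_filtering()
    once = bandpass_filter(ds)
    twice = bandpass_filter(once)
    assert abs(rms(twice.as_matrix()) - rms(once.as_matrix())) < 0.01 * rms(once.as_matrix())


def generate_domain_pair_for_filtering():
    eps = [generate_epoch(SOURCE_SIGNATURES["N2"], seed=11 + i) for i in range(3)]
    return DomainDataset("source", eps, SLEEP5, [0, 1, 2])


def test_bandpass_preserves_structure_and_labels():
    ds = generate_domain_pair_for_filtering()
    out = bandpass_filter(ds)
    assert len(out) == len(ds) and out.rate == ds.rate
    np.testing.assert_array_equal(out.labels, ds.labels)


def test_bandpass_nyquist_error():
    with pytest.raises(ParameterError):
        bandpass_filter(sine_dataset(10, rate=80), high=45.0)


# --------------------------------------------------------------------- ICA

def test_ica_improves_correlation_with_ground_truth(alpha_epochs):
    cont, clean = [], []
    for i, ep in enumerate(alpha_epochs):
        c, cl = inject_artifact(ep, "blink", 150.0, seed=200 + i)
        cont.append(c)
        clean.append(cl)
    ds = DomainDataset("source", cont, SLEEP5, None)
    out = remove_artifacts_ica(ds, n_components=8)

    def mean_corr(epochs):
        return np.mean([np.corrcoef(e.samples, cl.samples)[0, 1]
                        for e, cl in zip(epochs, clean)])

    assert mean_corr(out.epochs) > mean_corr(cont)


def test_ica_near_noop_on_clean_data(alpha_epochs):
    ds = DomainDataset("source", list(alpha_epochs), SLEEP5, None)
    out = remove_artifacts_ica(ds, n_components=8)
    diff = out.as_matrix() - ds.as_matrix()
    assert rms(diff) < 0.1 * rms(ds.as_matrix())


def test_ica_zero_input_noop():
    eps = [EEGEpoch(np.zeros(3000), 100.0)] * 4
    ds = DomainDataset("source", eps, SLEEP5, None)
    out = remove_artifacts_ica(ds, n_components=2)
    assert np.all(out.as_matrix() == 0)


def test_ica_component_budget_error(alpha_epochs):
    ds = DomainDataset("source", list(alpha_epochs[:1]), SLEEP5, None)
    with pytest.raises(ParameterError):
        remove_artifacts_ica(ds, n_components=1000)


def test_ica_preserves_shape_and_labels(alpha_epochs):
    ds = DomainDataset("source", list(alpha_epochs), SLEEP5,
                       np.arange(len(alpha_epochs)) % 5)
    out = remove_artifacts_ica(ds, n_components=6)
    assert out.as_matrix().shape == ds.as_matrix().shape
    np.testing.assert_array_equal(out.labels, ds.labels)


# ---------------------------------------------------------------- resample

def test_resample_counts():
    ds = sine_dataset(10.0, rate=128.0, length_s=30.0)
    out = resample(ds, 100.0)
    assert out.rate == 100.0
    assert out.epochs[0].n_samples == 3000


def test_resample_identity():
    ds = sine_dataset(10.0, rate=128.0)
    out = resample(ds, 128.0)
    np.testing.assert_array_equal(out.as_matrix(), ds.as_matrix())


def test_resample_preserves_dominant_frequency():
    ds = sine_dataset(10.0, rate=128.0, length_s=30.0)
    out = resample(ds, 100.0)
    spec = np.abs(np.fft.rfft(out.epochs[0].samples))
    freqs = np.fft.rfftfreq(out.epochs[0].n_samples, d=1 / 100.0)
    assert abs(freqs[spec.argmax()] - 10.0) < 0.2


def test_resample_bad_rate():
    with pytest.raises(ParameterError):
        resample(sine_dataset(10.0), -5)


# ----------------------------------------------------------------- text I/O

def test_epoch_text_roundtrip(tmp_path, domain_pair):
    src, _ = domain_pair
    small = DomainDataset("source", src.epochs[:4], SLEEP5, src.labels[:4])
    p = tmp_path / "epochs.tsv"
    save_epoch_text(p, small)
    back = load_epoch_text(p)
    assert back.domain == "source" and back.scheme.name == "sleep5"
    np.testing.assert_allclose(back.as_matrix(), small.as_matrix(), rtol=1e-4,
                               atol=1e-3)
    lp = tmp_path / "labels.tsv"
    save_labels(lp, small)
    labeled = load_labels(lp, back)
    np.testing.assert_array_equal(labeled.labels, small.labels)


def test_epoch_npz_roundtrip(tmp_path, domain_pair):
    _, tgt = domain_pair
    small = DomainDataset("target", tgt.epochs[:4], FATIGUE3, tgt.labels[:4])
    p = tmp_path / "epochs.npz"
    save_epoch_npz(p, small)
    back = load_epoch_npz(p)
    assert back.domain == "target" and back.scheme.name == "fatigue3"
    np.testing.assert_array_equal(back.as_matrix(), small.as_matrix())
    np.testing.assert_array_equal(back.labels, small.labels)
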