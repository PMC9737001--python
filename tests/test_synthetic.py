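import numpy as np
import pytest

from hospitalflow import default_config, sample_arrivals, sample_los
from hospitalflow.synthetic import sample_arrival_arrays


def _constant_rate_cfg(rate, stream="walk_in"):
    cfg = default_config()
    for k in cfg.arrival_rates:
        cfg.arrival_rates[k] = np.zeros((7, 24))
    cfg.arrival_rates[stream] = np.full((7, 24), rate)
    return cfg


def test_nonpositive_horizon_rejected(cfg):
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match="horizon"):
        sample_arrivals(cfg, 0, rng)
    with pytest.raises(ValueError, match="horizon"):
        sample_arrivals(cfg, -5, rng)


def test_zero_intensity_yields_no_arrivals():
    cfg = _constant_rate_cfg(0.0)
    assert sample_arrivals(cfg, 1, np.random.default_rng(0)) == []


def test_poisson_rate_recovered_at_large_horizon():
    """Count/horizon of a constant-rate stream matches lambda within 3 SE.

    Oracle: Poisson counts over T hours at rate 2/h have mean 2T and
    variance 2T, so the empirical rate has SE sqrt(2/T).
    """
    lam, T = 2.0, 10_000
    cfg = _constant_rate_cfg(lam)
    arr = sample_arrival_arrays(cfg, T, np.random.default_rng(42))
    se = np.sqrt(lam / T)
    assert arr["time"].size / T == pytest.approx(lam, abs=3 * se)


def test_arrival_times_sorted_and_within_horizon():
    cfg = default_config()
    arr = sample_arrival_arrays(cfg, 24 * 14, np.random.default_rng(3))
    assert (np.diff(arr["time"]) >= 0).all()
    assert arr["time"][0] >= 0 and arr["time"][-1] < 24 * 14


def test_all_ambulances_when_walk_in_stream_is_empty():
    cfg = default_config()
    cfg.arrival_rates["walk_in"] = np.zeros((7, 24))
    cfg.arrival_rates["elective"] = np.zeros((7, 24))
    cfg.ambulance_fraction = 1.0
    arrivals = sample_arrivals(cfg, 24 * 7, np.random.default_rng(0))
    assert arrivals and all(a.mode == "ambulance" for a in arrivals)


def test_triage_scores_in_range_and_electives_least_urgent(cfg):
    arr = sample_arrival_arrays(cfg, 24 * 30, np.random.default_rng(5))
    assert set(np.unique(arr["triage"])) <= {1, 2, 3, 4, 5}
    assert (arr["triage"][arr["mode"] == 2] == 5).all()


def test_electives_only_in_weekday_windows(cfg):
    arrivals = sample_arrivals(cfg, 24 * 28, np.random.default_rng(7))
    lo, hi = cfg.elective_window
    for a in arrivals:
        if a.mode == "elective":
            assert (a.time // 24) % 7 < 5  # Monday..Friday
            assert lo <= a.time % 24 < hi
            assert a.patient_class == "surgical"


def test_identical_seed_gives_bit_identical_streams(cfg):
    a = sample_arrival_arrays(cfg, 24 * 30, np.random.default_rng(11))
    b = sample_arrival_arrays(cfg, 24 * 30, np.random.default_rng(11))
    for k in a:
        np.testing.assert_array_equal(a[k], b[k])


def test_medical_surgical_ratio_converges(cfg):
    """Empirical admitted-class ratio approaches the configured 1.173."""
    rng = np.random.default_rng(1)
    arr = sample_arrival_arrays(cfg, 24 * 365 * 2, rng)
    ed = arr["mode"] != 2
    admit_p = cfg.admit_probability[arr["triage"][ed] - 1]
    admitted = rng.random(ed.sum()) < admit_p
    medical = (rng.random(ed.sum()) < cfg.class_split) & admitted
    n_med = medical.sum()
    n_surg = (admitted & ~medical).sum() + (~ed).sum()
    assert n_med / n_surg == pytest.approx(1.173, rel=0.05)


# ---------------------------------------------------------------------- LOS
def test_unknown_class_rejected(cfg):
    with pytest.raises(ValueError, match="ward_x"):
        sample_los(cfg, "ward_x", np.random.default_rng(0))


def test_zero_scale_degenerates_to_exp_mu(cfg):
    cfg2 = default_config()
    cfg2.los_params = {**cfg2.los_params, "medical": (np.log(100.0), 0.0)}
    for i in range(5):
        assert sample_los(cfg2, "medical", np.random.default_rng(i)) == pytest.approx(100.0)


def test_los_positive_and_mean_matches_lognormal_moment(cfg):
    """10k draws: sample mean within 3 SE of exp(mu + sigma^2/2)."""
    rng = np.random.default_rng(123)
    draws = np.array([sample_los(cfg, "medical", rng) for _ in range(10_000)])
    assert (draws > 0).all()
    mu, sigma = cfg.los_params["medical"]
    mean = np.exp(mu + sigma**2 / 2)
    sd = mean * np.sqrt(np.exp(sigma**2) - 1)
    assert draws.mean() == pytest.approx(mean, abs=3 * sd / 100.0)
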