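import pytest
from hypothesis import HealthCheck, settings

import triform as tf

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("det")


@pytest.fixture
def bed_file(tmp_path):
    """Factory writing a list of reads (or raw lines) to a BED file."""
    counter = {"n": 0}

    def _write(reads_or_lines, name=None):
        counter["n"] += 1
        path = tmp_path / (name or f"reads{counter['n']}.bed")
        if reads_or_lines and isinstance(reads_or_lines[0], str):
            path.write_text("\n".join(reads_or_lines) + "\n")
        else:
            tf.write_reads_bed(reads_or_lines, path)
        return path

    return _write


@pytest.fixture(scope="session")
def small_experiment(tmp_path_factory):
    """A small but signal-rich simulated experiment shared across tests.

    300 kb genome, 8 strong planted sites over realistic background
    density (the enrichment-ratio cut-off is a quantile of the Form-1
    population, so a realistic share of weak background regions is needed
    for it to sit below the true peaks); returns (chip_bed, control_bed,
    truth, config).
    """
    cfg = tf.SimConfig(genome=(("chr1", 300_000),), n_sites=8,
                       reads_per_site=60.0, background_rate=0.005,
                       control_rate=0.005, seed=11)
    chip, control, truth = tf.simulate_experiment(cfg)
    d = tmp_path_factory.mktemp("smallsim")
    chip_bed = d / "chip.bed"
    control_bed = d / "control.bed"
    tf.write_reads_bed(chip, chip_bed)
    tf.write_reads_bed(control, control_bed)
    return chip_bed, control_bed, truth, cfg
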