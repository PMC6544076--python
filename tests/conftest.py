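import numpy as np
import pytest

import prefbra as pb


@pytest.fixture(scope="session")
def study():
    """Packaged study configuration: attributes, profiles, transforms."""
    attributes, profiles, transforms = pb.load_study_config()
    return attributes, profiles, transforms


@pytest.fixture(scope="session")
def attributes(study):
    return study[0]


@pytest.fixture(scope="session")
def profiles(study):
    return study[1]


@pytest.fixture(scope="session")
def whole_sample_weights(attributes):
    return pb.weights_from_mean_mirs(pb.study_mean_mirs("all"), attributes)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_model(rng, n_attrs=5):
    """A random small value model: attributes, two profiles, raw weights."""
    attrs = [pb.Attribute(name="procedure", direction="benefit",
                          worst=0.0, best=1.0, units="binary-procedure")]
    for i in range(n_attrs):
        if rng.random() < 0.5:
            worst, best = sorted(rng.uniform(0, 1, size=2))
            direction, units = "benefit", "proportion"
        else:
            best, worst = sorted(rng.uniform(0, 1, size=2))
            direction, units = "risk", "proportion"
        attrs.append(pb.Attribute(name=f"a{i}", direction=direction,
                                  worst=worst, best=best, units=units))
    def profile(name):
        perf = {}
        for a in attrs:
            if a.units == "binary-procedure":
                perf[a.name] = pb.PerformanceEstimate(mean=float(rng.integers(2)))
            else:
                perf[a.name] = pb.PerformanceEstimate(
                    mean=float(rng.uniform(a.lower, a.upper)))
        return pb.AlternativeProfile(name=name, performance=perf)
    raw = {a.name: (1.0 if a.units == "binary-procedure"
                    else float(rng.uniform(0.1, 3.0))) for a in attrs}
    return attrs, profile("A"), profile("B"), raw
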