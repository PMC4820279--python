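"""satgrowth: enzyme-saturation-driven growth arrest and persistence.

Deterministic cost/benefit models of a saturable metabolic pathway, exact
stochastic simulation of the growth-feedback reaction network, metastable
population dynamics, and inference of growth-arrested subpopulations from
flow-cytometry, growth-curve and kill-curve measurements.
"""

__version__ = "0.1.0"

from . import meanfield, population, inference, synth  # noqa: F401,E402

__all__ = ["meanfield", "ssa", "population", "inference", "synth", "__version__"]


def __getattr__(name):
    # ssa imports numba (slow first import); load it lazily
    if name == "ssa":
        import importlib

        return importlib.import_module(".ssa", __name__)
    raise AttributeError(name)
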