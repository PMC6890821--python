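"""mdflex: flexibility metrics, essential-dynamics PCA, NMR-observable
validation and sphere-intersection pocket classification for
conformational ensembles."""

from importlib import resources

__version__ = "0.1.0"


def data_path(name: str):
    """Path to a packaged data table (TSV) shipped with mdflex."""
    return resources.files(__package__) / "data" / name


from . import (  # noqa: E402
    geometry,
    nmr_compare,
    pca_modes,
    pocket_mapper,
    structure_io,
    synthetic_data,
    traj_metrics,
)

__all__ = [
    "structure_io",
    "traj_metrics",
    "pca_modes",
    "geometry",
    "nmr_compare",
    "pocket_mapper",
    "synthetic_data",
    "data_path",
    "__version__",
]
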