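"""CF-convention NetCDF readers/writers for gridded fields.

Files use dimensions ``time``/``lat``/``lon`` (``month``/``lat``/``lon``
for the transpired fraction) and carry a ``units`` attribute per variable.
Column water vapor in ``kg m-2`` is accepted and treated as mm (the two are
identical for liquid water depth).
"""

from __future__ import annotations

import numpy as np
import xarray as xr

__all__ = ["read_gridded", "write_gridded"]

_ENGINE = "scipy"  # NETCDF3_64BIT; round-trips float64 bit-exactly

_CWV_MM_EQUIVALENT = {"mm", "kg m-2", "kg m**-2", "kg/m2", "kg/m^2"}
_KNOWN_UNITS = {
    "cwv": _CWV_MM_EQUIVALENT,
    "cwv_t": _CWV_MM_EQUIVALENT,
    "precip": {"mm h-1", "mm/h", "mm hr-1", "mm h**-1"},
    "precip_mc": {"mm h-1", "mm/h", "mm hr-1", "mm h**-1"},
    "ft": {"1", ""},
}
_CANONICAL_UNITS = {
    "cwv": "mm",
    "cwv_t": "mm",
    "precip": "mm h-1",
    "precip_mc": "mm h-1",
    "ft": "1",
}


def write_gridded(field: xr.Dataset | xr.DataArray, path) -> None:
    """Write a gridded field (or dataset of fields) to CF NetCDF."""
    ds = field.to_dataset() if isinstance(field, xr.DataArray) else field
    for name, var in ds.data_vars.items():
        if "units" not in var.attrs:
            if name in _CANONICAL_UNITS:
                var.attrs["units"] = _CANONICAL_UNITS[name]
            else:
                raise ValueError(f"variable {name!r} has no units attribute")
    ds.to_netcdf(path, engine=_ENGINE)


def read_gridded(
    path,
    required_dims: tuple[str, ...] = ("time", "lat", "lon"),
) -> xr.Dataset:
    """Read a CF NetCDF file, validating dimensions and units.

    Known variables with mm-equivalent units (``kg m-2`` for water vapor)
    are relabeled to the package's canonical units.  Raises ValueError
    naming any missing dimension or unit violation.
    """
    with xr.open_dataset(path, engine=_ENGINE) as handle:
        ds = handle.load()
    for dim in required_dims:
        if dim not in ds.dims:
            raise ValueError(f"file {path} is missing required dimension {dim!r}")
    for name, var in ds.data_vars.items():
        if name not in _KNOWN_UNITS:
            continue
        units = var.attrs.get("units")
        if units is None:
            raise ValueError(f"variable {name!r} in {path} has no units attribute")
        if units not in _KNOWN_UNITS[name]:
            raise ValueError(
                f"variable {name!r} in {path} has units {units!r}; "
                f"expected one of {sorted(_KNOWN_UNITS[name])}"
            )
        var.attrs["units"] = _CANONICAL_UNITS[name]
    return ds
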