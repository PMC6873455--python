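"""Price standardization: remove wage-index-driven geographic payment variation.

A paid amount from a provider in a zip with wage index ``w`` is deflated to a
national-average price level by dividing out the labor-share-weighted index:

    standardized = paid / (labor_share * w + (1 - labor_share))

so an amount from a region at the national average (``w = 1``) is unchanged,
high-wage regions are deflated and low-wage regions inflated.  This mirrors
inpatient-prospective-payment-style standardization in which only the labor
share of the payment scales with the local wage index.
"""

from __future__ import annotations

import numbers

import pandas as pd


class MissingZipError(KeyError):
    """A claim's provider zip is absent from the crosswalk."""


def standardize_payment(paid: float, wage_index: float, labor_share: float = 0.62) -> float:
    """Deflate one paid amount to the national price level.

    Inverse of the wage inflation applied when a payment is priced locally;
    identity when ``wage_index == 1``.
    """
    if wage_index <= 0:
        raise ValueError(f"wage_index must be > 0, got {wage_index}")
    if not 0.0 <= labor_share <= 1.0:
        raise ValueError(f"labor_share must lie in [0, 1], got {labor_share}")
    if isinstance(paid, numbers.Real) and paid < 0:
        raise ValueError(f"paid must be >= 0, got {paid}")
    return paid / (labor_share * wage_index + (1.0 - labor_share))


def standardize_claims(
    claims: pd.DataFrame,
    crosswalk: pd.DataFrame,
    labor_share: float = 0.62,
    permissive: bool = False,
) -> pd.DataFrame:
    """Replace every ``paid_amount`` with its standardized value.

    The original amount is retained in ``paid_amount_raw``.  Claims whose zip
    is missing from the crosswalk raise :class:`MissingZipError` naming the
    zips, unless ``permissive`` is set, in which case they pass through
    unstandardized and are flagged in the ``unstandardized`` column.
    """
    wage = crosswalk.set_index("zip")["wage_index"]
    if (wage <= 0).any():
        bad = wage.index[wage <= 0].tolist()
        raise ValueError(f"crosswalk has nonpositive wage_index for zips {bad}")
    out = claims.copy()
    w = out["provider_zip"].map(wage)
    missing = w.isna()
    if missing.any() and not permissive:
        zips = sorted(out.loc[missing, "provider_zip"].unique().tolist())
        raise MissingZipError(f"zips missing from crosswalk: {zips}")
    factor = labor_share * w + (1.0 - labor_share)
    out["paid_amount_raw"] = out["paid_amount"]
    out["paid_amount"] = out["paid_amount_raw"] / factor
    out["unstandardized"] = missing.astype(int)
    out.loc[missing, "paid_amount"] = out.loc[missing, "paid_amount_raw"]
    return out
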