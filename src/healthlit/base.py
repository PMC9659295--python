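"""Minimal estimator base: sklearn-compatible parameter handling.

Estimators take all hyperparameters as keyword constructor arguments,
store them unchanged, and expose fitted results as attributes with a
trailing underscore.  ``get_params``/``set_params`` follow the sklearn
contract, so the estimators clone and grid-search correctly.
"""

from __future__ import annotations

import inspect


class BaseEstimator:
    @classmethod
    def _param_names(cls):
        sig = inspect.signature(cls.__init__)
        return [p.name for p in sig.parameters.values()
                if p.name != "self" and p.kind != p.VAR_KEYWORD]

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names()}

    def set_params(self, **params):
        valid = set(self._param_names())
        for key, value in params.items():
            if key not in valid:
                raise ValueError(f"invalid parameter {key!r} for {type(self).__name__}")
            setattr(self, key, value)
        return self

    def __repr__(self):
        args = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({args})"


def check_is_fitted(estimator, attribute: str) -> None:
    if not hasattr(estimator, attribute):
        raise RuntimeError(
            f"{type(estimator).__name__} is not fitted yet; call fit first")
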