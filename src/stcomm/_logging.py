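import logging

_CONFIGURED = False


def get_logger(name: str = "stcomm") -> logging.Logger:
    return logging.getLogger(name)


def configure(level: str = "INFO") -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    global _CONFIGURED
    logger = logging.getLogger("stcomm")
    logger.setLevel(level.upper())
    if not _CONFIGURED:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s: %(message)s")
        )
        logger.addHandler(handler)
        _CONFIGURED = True
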