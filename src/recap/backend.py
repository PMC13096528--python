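"""The four-operation model-backend contract: describe, classify, reflect, modify.

Any backend — a remote multimodal API, a record/replay transcript store, or
the deterministic simulated backend used for testing — implements the same
four operations:

* ``describe(image, q)``: generate a textual description s of an image
  under generation prompt q (s = MLLM(x, q)).
* ``classify(image, p, s)``: produce raw label text from the classification
  prompt concatenated with the description (y_hat = MLLM(x, [p, s])).
* ``reflect(p, errors, template)``: free-text diagnosis of failure modes
  from a subset of misclassified examples.
* ``modify(p, reflection, errors, template, parent_text)``: revised
  generation-prompt text informed by the reflection.

The base class enforces preconditions, logs every call, and guarantees
non-empty replies; concrete backends implement the ``_``-prefixed hooks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from abc import ABC, abstractmethod
from pathlib import Path
from typing import Optional, Sequence

from .corpus import LabeledImage
from .prompts import Prompt, PromptRole
from .scoring import ErrorEntry

DESCRIBE_TEMPERATURE = 0.7  # creative description generation
CLASSIFY_TEMPERATURE = 0.0  # deterministic prediction
REFLECT_TEMPERATURE = 0.7
MODIFY_TEMPERATURE = 0.7

DEFAULT_REFLECTION_TEMPLATE_TEXT = (
    "You are reviewing misclassified pathology cases. For each case below, the "
    "generated description and the incorrect prediction are shown:\n{errors}\n"
    "Reflect on the failure modes: which morphological features were missed or "
    "misweighted, and what sources of diagnostic confusion are likely?\n"
    "Expert notes (optional): {expert_notes}"
)

DEFAULT_MODIFICATION_TEMPLATE_TEXT = (
    "The current description-generation instructions are:\n{current_prompt}\n"
    "A reflection on recent misclassifications concluded:\n{reflection}\n"
    "Rewrite the instructions so the resulting descriptions address these failure "
    "modes while staying clinically coherent."
)

DIVERSIFY_MODIFICATION_TEMPLATE_TEXT = (
    "The current description-generation instructions are:\n{current_prompt}\n"
    "A reflection on recent misclassifications concluded:\n{reflection}\n"
    "Rewrite the instructions to address these failure modes and additionally "
    "introduce novel terminology: explore alternative morphological perspectives "
    "and varied interpretive lenses beyond the current wording."
)


class BackendError(RuntimeError):
    """A backend returned an unusable reply."""


class RetriableBackendError(BackendError):
    """Transport-level failure; the call may be retried."""


class TemplateError(ValueError):
    """A reflection/modification template is missing a required placeholder."""


@dataclasses.dataclass(frozen=True)
class BackendRequest:
    """Canonical form of one backend call, used for logging and transcripts."""

    operation: str  # describe | classify | reflect | modify
    text_parts: tuple[str, ...]
    image_id: Optional[str] = None
    image_digest: Optional[str] = None
    temperature: float = 0.0

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()


@dataclasses.dataclass(frozen=True)
class BackendReply:
    text: str
    meta: tuple[tuple[str, str], ...] = ()


@dataclasses.dataclass(frozen=True)
class CallRecord:
    operation: str
    prompt_id: Optional[str]
    image_id: Optional[str]
    temperature: float


class CallLog:
    """Append-only record of every backend call in a run."""

    def __init__(self) -> None:
        self.records: list[CallRecord] = []

    def add(self, record: CallRecord) -> None:
        self.records.append(record)

    def count(self, operation: Optional[str] = None) -> int:
        if operation is None:
            return len(self.records)
        return sum(1 for r in self.records if r.operation == operation)

    def describe_calls_per_prompt(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            if r.operation == "describe" and r.prompt_id is not None:
                out[r.prompt_id] = out.get(r.prompt_id, 0) + 1
        return out


def image_digest(image: LabeledImage) -> str:
    """Stable digest of an image payload (latent features or file bytes)."""
    h = hashlib.sha256()
    h.update(image.id.encode("utf-8"))
    if image.features is not None:
        h.update(bytes(image.features))
    elif image.image_ref and Path(image.image_ref).exists():
        h.update(Path(image.image_ref).read_bytes())
    return h.hexdigest()


def _format_errors(errors: Sequence[ErrorEntry]) -> str:
    lines = []
    for e in errors:
        lines.append(
            f"- image {e.image_id}: true={e.true_label}, predicted={e.predicted_label}\n"
            f"  description: {e.description}"
        )
    return "\n".join(lines)


class MLLMBackend(ABC):
    """Base class enforcing the call contract and logging every call."""

    def __init__(self) -> None:
        self.log = CallLog()

    # -- public contract -------------------------------------------------
    def describe(
        self, image: LabeledImage, generation_prompt: Prompt, temperature: float = DESCRIBE_TEMPERATURE
    ) -> str:
        if generation_prompt.role is not PromptRole.GENERATION:
            raise ValueError(
                f"describe requires a generation prompt, got role {generation_prompt.role.value}"
            )
        self.log.add(CallRecord("describe", generation_prompt.id, image.id, temperature))
        text = self._describe(image, generation_prompt, temperature)
        if not text:
            raise BackendError(
                f"empty describe reply for prompt {generation_prompt.id}, image {image.id}"
            )
        return text

    def classify(
        self,
        image: LabeledImage,
        classification_prompt: Prompt,
        description: str,
        temperature: float = CLASSIFY_TEMPERATURE,
    ) -> str:
        if classification_prompt.role is not PromptRole.CLASSIFICATION:
            raise ValueError(
                f"classify requires a classification prompt, got role {classification_prompt.role.value}"
            )
        self.log.add(CallRecord("classify", classification_prompt.id, image.id, temperature))
        text = self._classify(image, classification_prompt, description, temperature)
        if not text:
            raise BackendError(f"empty classify reply for image {image.id}")
        return text

    def reflect(
        self,
        classification_prompt: Prompt,
        error_subset: Sequence[ErrorEntry],
        template: Prompt,
        temperature: float = REFLECT_TEMPERATURE,
        expert_notes: str = "",
    ) -> str:
        if not error_subset:
            raise ValueError("reflect requires a non-empty error subset")
        if template.role is not PromptRole.REFLECTION_TEMPLATE:
            raise ValueError(f"reflect requires a reflection template, got {template.role.value}")
        if "{errors}" not in template.text:
            raise TemplateError("reflection template must contain an {errors} placeholder")
        self.log.add(CallRecord("reflect", classification_prompt.id, None, temperature))
        rendered = template.text.replace("{errors}", _format_errors(error_subset)).replace(
            "{expert_notes}", expert_notes or "none"
        )
        text = self._reflect(classification_prompt, error_subset, rendered, temperature)
        if not text:
            raise BackendError("empty reflect reply")
        return text

    def modify(
        self,
        classification_prompt: Prompt,
        reflection: str,
        error_subset: Sequence[ErrorEntry],
        template: Prompt,
        current_generation_prompt: Prompt,
        temperature: float = MODIFY_TEMPERATURE,
    ) -> str:
        if template.role is not PromptRole.MODIFICATION_TEMPLATE:
            raise ValueError(f"modify requires a modification template, got {template.role.value}")
        for placeholder in ("{reflection}", "{current_prompt}"):
            if placeholder not in template.text:
                raise TemplateError(f"modification template must contain a {placeholder} placeholder")
        self.log.add(CallRecord("modify", current_generation_prompt.id, None, temperature))
        rendered = template.text.replace("{reflection}", reflection).replace(
            "{current_prompt}", current_generation_prompt.text
        )
        text = self._modify(
            classification_prompt, reflection, error_subset, rendered, current_generation_prompt, temperature
        )
        if not text:
            raise BackendError("empty modify reply")
        return text

    # -- hooks ------------------------------------------------------------
    @abstractmethod
    def _describe(self, image: LabeledImage, prompt: Prompt, temperature: float) -> str: ...

    @abstractmethod
    def _classify(
        self, image: LabeledImage, prompt: Prompt, description: str, temperature: float
    ) -> str: ...

    @abstractmethod
    def _reflect(
        self, prompt: Prompt, error_subset: Sequence[ErrorEntry], rendered: str, temperature: float
    ) -> str: ...

    @abstractmethod
    def _modify(
        self,
        prompt: Prompt,
        reflection: str,
        error_subset: Sequence[ErrorEntry],
        rendered: str,
        parent: Prompt,
        temperature: float,
    ) -> str: ...


class TranscriptStore:
    """One JSON file per request digest; makes vendor drift detectable."""

    def __init__(self, directory: str | Path) -> None:
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    def _path(self, request: BackendRequest) -> Path:
        return self.directory / f"{request.digest()}.json"

    def put(self, request: BackendRequest, reply: BackendReply) -> None:
        payload = {"request": dataclasses.asdict(request), "reply": dataclasses.asdict(reply)}
        self._path(request).write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")

    def get(self, request: BackendRequest) -> Optional[BackendReply]:
        path = self._path(request)
        if not path.exists():
            return None
        data = json.loads(path.read_text(encoding="utf-8"))
        reply = data["reply"]
        return BackendReply(text=reply["text"], meta=tuple(tuple(kv) for kv in reply.get("meta", ())))


class _RequestBuilder:
    @staticmethod
    def describe(image: LabeledImage, prompt: Prompt, temperature: float) -> BackendRequest:
        return BackendRequest(
            "describe", (prompt.text,), image.id, image_digest(image), temperature
        )

    @staticmethod
    def classify(
        image: LabeledImage, prompt: Prompt, description: str, temperature: float
    ) -> BackendRequest:
        return BackendRequest(
            "classify", (prompt.text, description), image.id, image_digest(image), temperature
        )

    @staticmethod
    def text_op(operation: str, rendered: str, temperature: float) -> BackendRequest:
        return BackendRequest(operation, (rendered,), None, None, temperature)


class RecordingBackend(MLLMBackend):
    """Wraps another backend and records every request/reply as a transcript."""

    def __init__(self, inner: MLLMBackend, store: TranscriptStore) -> None:
        super().__init__()
        self.inner = inner
        self.store = store

    def _record(self, request: BackendRequest, text: str) -> str:
        self.store.put(request, BackendReply(text=text))
        return text

    def _describe(self, image, prompt, temperature):
        text = self.inner._describe(image, prompt, temperature)
        return self._record(_RequestBuilder.describe(image, prompt, temperature), text)

    def _classify(self, image, prompt, description, temperature):
        text = self.inner._classify(image, prompt, description, temperature)
        return self._record(_RequestBuilder.classify(image, prompt, description, temperature), text)

    def _reflect(self, prompt, error_subset, rendered, temperature):
        text = self.inner._reflect(prompt, error_subset, rendered, temperature)
        return self._record(_RequestBuilder.text_op("reflect", rendered, temperature), text)

    def _modify(self, prompt, reflection, error_subset, rendered, parent, temperature):
        text = self.inner._modify(prompt, reflection, error_subset, rendered, parent, temperature)
        return self._record(_RequestBuilder.text_op("modify", rendered, temperature), text)


class ReplayMissError(BackendError):
    """A replayed run requested a transcript that was never recorded."""


class ReplayBackend(MLLMBackend):
    """Serves recorded transcripts; raises on any unrecorded request."""

    def __init__(self, store: TranscriptStore) -> None:
        super().__init__()
        self.store = store

    def _serve(self, request: BackendRequest) -> str:
        reply = self.store.get(request)
        if reply is None:
            raise ReplayMissError(f"no transcript for {request.operation} request {request.digest()}")
        return reply.text

    def _describe(self, image, prompt, temperature):
        return self._serve(_RequestBuilder.describe(image, prompt, temperature))

    def _classify(self, image, prompt, description, temperature):
        return self._serve(_RequestBuilder.classify(image, prompt, description, temperature))

    def _reflect(self, prompt, error_subset, rendered, temperature):
        return self._serve(_RequestBuilder.text_op("reflect", rendered, temperature))

    def _modify(self, prompt, reflection, error_subset, rendered, parent, temperature):
        return self._serve(_RequestBuilder.text_op("modify", rendered, temperature))


class HTTPChatBackend(MLLMBackend):
    """Thin JSON-over-HTTP adapter for chat-completions style endpoints.

    Network behavior is deliberately outside the automated test surface;
    tests run against the simulated or replay backends. Retries are bounded
    with exponential backoff. The API key is read from an environment
    variable, never from config files.
    """

    def __init__(
        self,
        endpoint: str,
        model: str,
        api_key_env: str = "RECAP_API_KEY",
        max_retries: int = 3,
        backoff_seconds: float = 1.0,
        timeout_seconds: float = 60.0,
        image_preprocessor=None,
    ) -> None:
        super().__init__()
        self.endpoint = endpoint
        self.model = model
        self.api_key_env = api_key_env
        self.max_retries = max_retries
        self.backoff_seconds = backoff_seconds
        self.timeout_seconds = timeout_seconds
        # hook: image bytes -> encoded payload; resizing policy is caller's choice
        self.image_preprocessor = image_preprocessor or (lambda raw: raw)

    def _post(self, payload: dict) -> str:  # pragma: no cover - network
        import os
        import urllib.error
        import urllib.request

        key = os.environ.get(self.api_key_env, "")
        req = urllib.request.Request(
            self.endpoint,
            data=json.dumps(payload).encode("utf-8"),
            headers={"Content-Type": "application/json", "Authorization": f"Bearer {key}"},
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout_seconds) as resp:
                body = json.loads(resp.read().decode("utf-8"))
        except (urllib.error.URLError, TimeoutError) as exc:
            raise RetriableBackendError(str(exc)) from exc
        return body["choices"][0]["message"]["content"]

    def _post_with_retries(self, payload: dict) -> str:
        attempt = 0
        while True:
            try:
                return self._post(payload)
            except RetriableBackendError:
                attempt += 1
                if attempt >= self.max_retries:
                    raise
                time.sleep(self.backoff_seconds * (2 ** (attempt - 1)))

    def _image_part(self, image: LabeledImage) -> dict:
        import base64

        if not image.image_ref:
            raise BackendError(f"image {image.id} has no file reference for a remote backend")
        raw = self.image_preprocessor(Path(image.image_ref).read_bytes())
        return {
            "type": "image_url",
            "image_url": {"url": "data:image/png;base64," + base64.b64encode(raw).decode("ascii")},
        }

    def _chat(self, parts: list[dict], temperature: float) -> str:
        return self._post_with_retries(
            {
                "model": self.model,
                "temperature": temperature,
                "messages": [{"role": "user", "content": parts}],
            }
        )

    def _describe(self, image, prompt, temperature):
        return self._chat([{"type": "text", "text": prompt.text}, self._image_part(image)], temperature)

    def _classify(self, image, prompt, description, temperature):
        text = prompt.text if not description else f"{prompt.text}\n\nDescription:\n{description}"
        return self._chat([{"type": "text", "text": text}, self._image_part(image)], temperature)

    def _reflect(self, prompt, error_subset, rendered, temperature):
        return self._chat([{"type": "text", "text": rendered}], temperature)

    def _modify(self, prompt, reflection, error_subset, rendered, parent, temperature):
        return self._chat([{"type": "text", "text": rendered}], temperature)
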