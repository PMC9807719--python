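"""Audit the canonical classifier: shapes, parameters, and MAC costs.

Builds the 13-layer bottleneck CNN spec, prints its per-layer audit, and
shows the cost arithmetic that motivates the 1x1 bottleneck design.
"""

import io

from tumorcnn import audit, conv2d, fast_tumor_cnn_spec, layer_cost

spec = fast_tumor_cnn_spec(include_bottlenecks=True)
rep = audit(spec)

buf = io.StringIO()
rep.to_csv(buf)
print(buf.getvalue().rstrip())
print(f"\nTotal parameters: {rep.total_params:,}   depth: {rep.depth}")

# why the 1x1 layers are there: a 3x3, 32-filter conv on a (256,256,32)
# input costs ~595M multiplies; shrinking to 10 channels first cuts the
# pair's cost (both stages costed on the 254x254 output grid) to ~206M.
plain = layer_cost(conv2d(3, 32), (256, 256, 32))
pair = layer_cost(conv2d(1, 10), (254, 254, 32)) + layer_cost(conv2d(3, 32), (256, 256, 10))
print(f"plain 3x3x32 cost:        {plain:,} MACs")
print(f"1x1x10 bottleneck + 3x3:  {pair:,} MACs ({100 * pair / plain:.1f}% of plain)")

ablation = audit(fast_tumor_cnn_spec(include_bottlenecks=False))
print(f"without 1x1 layers: {ablation.total_params:,} parameters "
      f"({ablation.total_params / rep.total_params:.1f}x the bottleneck model)")
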