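a
an
and
or
of
the
in
on
at
by
to
for
with
without
due
from
other
unspecified
nos
not
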