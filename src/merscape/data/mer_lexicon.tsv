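symbol	keyword
merA	mercuric reductase
merB	organomercurial lyase
merB	alkylmercury lyase
merR	mercuric resistance operon regulatory
merR	regulatory protein merr
merT	mercuric transport protein mert
merP	periplasmic mercuric
merP	binding protein merp
merC	transport protein merc
merF	transport protein merf
merD	co-regulator merd
merD	regulatory protein merd
merE	transporter mere
merE	broad-spectrum mercury transporter
merG	resistance protein merg
merG	phenylmercury resistance
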