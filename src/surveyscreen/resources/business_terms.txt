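# Address tokens suggesting a business rather than a residence
llc
inc
corp
corporation
company
ltd
enterprises
warehouse
distribution center
outlet
superstore
mall
plaza
headquarters
hq
store
shop
office park
industrial
logistics
holdings
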