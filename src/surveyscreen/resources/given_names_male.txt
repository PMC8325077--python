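# Common US male given names, roughly frequency-ranked
james
robert
john
michael
david
william
richard
joseph
thomas
charles
christopher
daniel
matthew
anthony
mark
donald
steven
paul
andrew
joshua
kenneth
kevin
brian
george
timothy
ronald
edward
jason
jeffrey
ryan
jacob
gary
nicholas
eric
jonathan
stephen
larry
justin
brandon
benjamin
samuel
gregory
frank
alexander
raymond
patrick
jack
dennis
jerry
tyler
aaron
jose
adam
nathan
henry
douglas
zachary
peter
kyle
ethan
walter
noah
jeremy
christian
keith
roger
terry
gerald
harold
sean
austin
carl
arthur
lawrence
dylan
jesse
jordan
bryan
billy
joe
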